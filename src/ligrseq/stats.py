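"""Hypergeometric enrichment testing of interaction pairs.

For a pair (A, B) with k chimeric reads, marginal counts K (all interaction
reads involving A, including k) and n (likewise for B), and N total
inter-feature interaction reads, the raw P-value is the one-sided upper
tail P(X >= k) for X ~ Hypergeometric(N, K, n): the chance of seeing at
least k A-B chimeras if B's reads picked partners at random from the
library. Raw P-values are adjusted with Benjamini-Hochberg step-up, and two
nested significant sets (raw < 0.05, FDR < 0.05) are extracted.

Only enrichment is tested (one-sided); self-pairs are intramolecular by
construction and never tested; N excludes intramolecular counts by default
(a ``total`` override lets the caller count the whole library instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma

import numpy as np
import pandas as pd

from .assign import (InteractionMatrix, assign_reads, build_interaction_matrix,
                     class_tally, merge_replicates, read_sam, sam_chrom_lengths)
from .features import FeatureTable, load_annotation, make_ua_features

RESULT_COLUMNS = ["featureA", "featureB", "k", "K", "n", "N",
                  "p_raw", "p_adj", "significant_raw", "significant_fdr"]


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Exact one-sided upper-tail P(X >= k), X ~ Hypergeometric(N, K, n).

    Computed from a log-gamma starting term and a multiplicative recurrence
    over whichever tail is shorter, so it is numerically stable for tiny
    tail probabilities and cheap for large counts. Symmetric in (K, n).
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v != int(v) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValueError(f"marginals exceed total: K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    lo = max(0, K + n - N)
    hi = min(K, n)
    if k <= lo:
        return 1.0

    log_denom = _log_comb(N, n)

    def logpmf(x: int) -> float:
        return _log_comb(K, x) + _log_comb(N - K, n - x) - log_denom

    def ratio(x: int) -> float:
        # pmf(x+1)/pmf(x)
        return ((K - x) * (n - x)) / ((x + 1) * (N - K - n + x + 1))

    mode = (K + 1) * (n + 1) // (N + 2)
    if k > mode or hi - k <= k - 1 - lo:
        # sum the upper tail directly; above the mode the terms decay
        # geometrically, so tiny tails never suffer cancellation
        t = exp(logpmf(k))
        s = t
        for x in range(k, hi):
            t *= ratio(x)
            s += t
            if x >= mode and t < s * 1e-18:
                break
        return min(1.0, s)
    # k at or below the mode: P(X >= k) is large, the complement is safe
    t = exp(logpmf(lo))
    s = t
    for x in range(lo, k - 1):
        t *= ratio(x)
        s += t
    return min(1.0, max(0.0, 1.0 - s))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order.

    Sort ascending, q_i = p_i * m / i, enforce monotone non-decreasing from
    the largest p downward, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    ecdf = np.arange(1, m + 1) / m
    raw = ranked / ecdf
    adj = np.minimum.accumulate(raw[::-1])[::-1]
    adj[adj > 1] = 1.0
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


@dataclass(frozen=True)
class InteractionResult:
    featureA: str
    featureB: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    significant_raw: bool
    significant_fdr: bool


def test_all_pairs(
    matrix: InteractionMatrix,
    min_count: int = 1,
    raw_alpha: float = 0.05,
    fdr: float = 0.05,
    total: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric test of every observed pair with k >= min_count.

    K and n are total interaction-class counts involving each partner
    (including k itself); N is the matrix total (interaction reads only)
    unless *total* overrides it with a whole-library count.
    """
    pc = matrix.pair_counts
    pc = pc[pc["count"] >= min_count]
    if matrix.N == 0 or pc.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    K = matrix.marginals()
    N = int(total) if total is not None else matrix.N
    kk = pc["count"].to_numpy()
    KA = pc["featureA"].map(K).to_numpy()
    KB = pc["featureB"].map(K).to_numpy()
    p_raw = np.array([hypergeom_pvalue(k, Ka, Kb, N)
                      for k, Ka, Kb in zip(kk, KA, KB)])
    p_adj = bh_adjust(p_raw)
    out = pd.DataFrame({
        "featureA": pc["featureA"].to_numpy(),
        "featureB": pc["featureB"].to_numpy(),
        "k": kk, "K": KA, "n": KB, "N": N,
        "p_raw": p_raw, "p_adj": p_adj,
        "significant_raw": p_raw < raw_alpha,
        "significant_fdr": p_adj < fdr,
    })
    return out.sort_values(["p_raw", "featureA", "featureB"],
                           kind="mergesort").reset_index(drop=True)


def extract_significant(results: pd.DataFrame, raw_alpha: float = 0.05,
                        fdr: float = 0.05):
    """Nested significant sets (FDR subset of raw), ordered by (p_raw, pair)."""
    r = results.sort_values(["p_raw", "featureA", "featureB"], kind="mergesort")
    raw = [(a, b) for a, b in
           zip(r.loc[r["p_raw"] < raw_alpha, "featureA"],
               r.loc[r["p_raw"] < raw_alpha, "featureB"])]
    sig = [(a, b) for a, b in
           zip(r.loc[r["p_adj"] < fdr, "featureA"],
               r.loc[r["p_adj"] < fdr, "featureB"])]
    return raw, sig


# ---------------------------------------------------------------------------
# hybridization-prediction input windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionWindow:
    feature_id: str
    sequence: str
    window_rule: str  # 'annotated_utr' | 'flank50'
    start: int
    end: int
    strand: str


def prediction_window(
    feature_id: str,
    features: FeatureTable,
    genome,
    utr_links: dict[str, list[str]] | None = None,
    flank: int = 50,
) -> PredictionWindow:
    """Sequence window handed to an external hybridization predictor.

    If UTR features are linked to the gene, the window spans the
    UTR-extended transcript; otherwise the gene span is extended *flank* nt
    each side, clipped at chromosome ends. The sequence is extracted on the
    feature strand (reverse-complemented for '-').
    """
    f = features.feature(feature_id)
    linked = (utr_links or {}).get(feature_id, [])
    if linked:
        spans = [features.feature(u) for u in linked] + [f]
        start = min(int(s.start) for s in spans)
        end = max(int(s.end) for s in spans)
        rule = "annotated_utr"
    else:
        start = max(1, int(f.start) - flank)
        end = min(genome.length, int(f.end) + flank)
        rule = "flank50"
    strand = f.strand if f.strand in ("+", "-") else "+"
    seq = genome.fetch(start, end, strand)
    return PredictionWindow(feature_id, seq, rule, start, end, strand)


def write_windows(windows, path) -> None:
    """FASTA output (headers = feature ids) for external predictors."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.feature_id}\n{w.sequence}\n")


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------

def call_interactions_end_to_end(
    sam_paths,
    gff,
    chrom_lengths: dict[str, int] | None = None,
    distance_threshold: int = 2000,
    junction_gap: int = 50,
    circular: bool = False,
    min_ua_length: int = 30,
    min_count: int = 1,
    raw_alpha: float = 0.05,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Annotation + replicate SAMs -> merged matrix -> tested pairs.

    Runs load_annotation -> make_ua_features -> assign_read ->
    build/merge matrices -> test_all_pairs -> bh_adjust. Returns the result
    table and a run log dict with per-replicate class tallies.
    """
    sam_paths = list(sam_paths)
    annotated = load_annotation(gff)
    if chrom_lengths is None:
        if not sam_paths:
            raise ValueError("chrom_lengths required when no SAM files are given")
        chrom_lengths = sam_chrom_lengths(sam_paths[0])
    features = make_ua_features(annotated, chrom_lengths, min_ua_length)
    matrices, tallies = [], {}
    for path in sam_paths:
        alignments = read_sam(path)
        calls = assign_reads(alignments, features, distance_threshold,
                             junction_gap, circular, chrom_lengths)
        tallies[str(path)] = class_tally(calls)
        matrices.append(build_interaction_matrix(calls, features,
                                                 label=str(path)))
    if matrices:
        merged = merge_replicates(matrices) if len(matrices) > 1 else matrices[0]
    else:
        merged = build_interaction_matrix([], features)
    results = test_all_pairs(merged, min_count=min_count,
                             raw_alpha=raw_alpha, fdr=fdr)
    info = {"tallies": tallies, "N": merged.N,
            "n_pairs_tested": int(len(results))}
    return results, info
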