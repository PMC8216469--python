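"""Simulation-to-results orchestration used by tests, examples and scripts.

Runs the full inference chain on synthetic libraries without touching disk:
feature generation, abundance draw, per-replicate ligation truth, alignment
segments at truth coordinates, vectorised classification, replicate
merging and hypergeometric testing. The file-based equivalent (SAM + GFF3
in, TSV out) is :func:`ligrseq.stats.call_interactions_end_to_end`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assign import (InteractionMatrix, assign_frame, build_interaction_matrix,
                     class_tally, merge_replicates)
from .features import FeatureTable, make_ua_features
from .simulate import (SimConfig, _generate_features, choose_planted_pairs,
                       draw_abundances, simulate_truth, truth_segments_frame)
from .stats import extract_significant, test_all_pairs


@dataclass
class SimulationRun:
    config: SimConfig
    features: FeatureTable          # annotated + UA
    abundances: pd.Series
    truth: pd.DataFrame             # all replicates
    calls: pd.DataFrame
    matrix: InteractionMatrix       # replicate-merged
    results: pd.DataFrame
    tallies: dict

    @property
    def planted(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b, _ in self.config.planted_pairs}

    def significant_sets(self, raw_alpha: float = 0.05, fdr: float = 0.05):
        return extract_significant(self.results, raw_alpha, fdr)


def plant_pairs(config: SimConfig, n_pairs: int, enrichment_fold: float,
                min_separation: int = 2000) -> SimConfig:
    """Return a config with planted pairs chosen from its own genome draw."""
    from dataclasses import replace
    rng = np.random.default_rng(config.seed)
    features = _generate_features(config, rng)
    abundances = draw_abundances(features, config)
    pairs = choose_planted_pairs(
        features, abundances, n_pairs, enrichment_fold,
        np.random.default_rng(config.seed + 10_007),
        min_separation=min_separation,
    )
    return replace(config, planted_pairs=pairs)


def run_simulation(
    config: SimConfig,
    distance_threshold: int = 2000,
    junction_gap: int = 50,
    min_count: int = 1,
    raw_alpha: float = 0.05,
    fdr: float = 0.05,
    min_ua_length: int = 30,
) -> SimulationRun:
    """Simulate all replicates and run the interaction-calling chain."""
    rng = np.random.default_rng(config.seed)
    annotated = _generate_features(config, rng)
    abundances = draw_abundances(annotated, config)
    chrom_lengths = {config.chrom: config.genome_length}
    features = make_ua_features(annotated, chrom_lengths, min_ua_length)

    truths, matrices, tallies, all_calls = [], [], {}, []
    for rep in range(1, config.replicate_count + 1):
        truth = simulate_truth(config, annotated, abundances, replicate=rep)
        truths.append(truth)
        segments = truth_segments_frame(truth, annotated)
        calls = assign_frame(segments, features, distance_threshold,
                             junction_gap, config.circular, chrom_lengths)
        tallies[rep] = class_tally(calls)
        all_calls.append(calls.assign(replicate=rep))
        matrices.append(build_interaction_matrix(calls, features,
                                                 label=f"rep{rep}"))
    matrix = merge_replicates(matrices) if len(matrices) > 1 else matrices[0]
    results = test_all_pairs(matrix, min_count=min_count,
                             raw_alpha=raw_alpha, fdr=fdr)
    truth = pd.concat(truths, ignore_index=True)
    calls = pd.concat(all_calls, ignore_index=True)
    return SimulationRun(config, features, abundances, truth, calls,
                         matrix, results, tallies)


def truth_pair_counts(truth: pd.DataFrame, features: FeatureTable,
                      distance_threshold: int = 2000,
                      junction_gap: int = 50,
                      circular: bool = True,
                      chrom_lengths: dict[str, int] | None = None
                      ) -> pd.DataFrame:
    """Ground-truth interaction pair counts under the same distance rules.

    Counts truth chimeras joining two distinct features whose edge
    separation exceeds the threshold — the counts a perfect classifier
    should recover.
    """
    from .assign import _feature_gap

    span = features.df.set_index("id")
    chim = truth[truth["feat2"].notna() & (truth["feat1"] != truth["feat2"])]
    rows = []
    gap_cache: dict[tuple[str, str], int] = {}
    for f1, f2 in zip(chim["feat1"], chim["feat2"]):
        a, b = sorted((f1, f2))
        if (a, b) not in gap_cache:
            clen = (chrom_lengths or {}).get(span.loc[a, "chrom"])
            gap_cache[(a, b)] = _feature_gap(span.loc[a], span.loc[b],
                                             circular, clen)
        if gap_cache[(a, b)] > distance_threshold:
            rows.append((a, b))
    if not rows:
        return pd.DataFrame(columns=["featureA", "featureB", "count"])
    return (pd.DataFrame(rows, columns=["featureA", "featureB"])
            .groupby(["featureA", "featureB"]).size()
            .rename("count").reset_index())
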