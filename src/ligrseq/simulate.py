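"""Synthetic proximity-ligation libraries with known ground truth.

Emulates the library design of an in-vivo psoralen-crosslinking /
proximity-ligation experiment on a small bacterial-style genome: a compact
annotation of genes and sRNAs, heavy-tailed per-feature abundances,
non-chimeric reads, intramolecular chimeras, abundance-proportional
background ligation between random transcript pairs, and a configurable set
of planted pairs ligated at an elevated rate. Every read carries a truth
record so downstream classification and enrichment testing can be scored
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .features import FeatureTable

log = logging.getLogger(__name__)

TRUTH_CLASSES = ("non_chimeric", "intramolecular", "background_pair", "planted_pair")

TRUTH_COLUMNS = [
    "read_id", "replicate", "cls",
    "feat1", "start1", "end1", "strand1",
    "feat2", "start2", "end2", "strand2",
]


class SimSizeError(ValueError):
    """Configured features cannot fit in the genome."""


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic library.

    Defaults describe a desk-scale version of a duplicate bacterial
    crosslinking library: one circular chromosome, a few dozen genes plus a
    handful of sRNAs, log-normal abundances, RNase-digested fragments of
    25-60 nt and single-end chimeric reads.
    """

    genome_length: int = 100_000
    n_genes: int = 60
    n_srnas: int = 10
    abundance_lognormal_mu_sigma: tuple[float, float] = (0.0, 1.0)
    n_reads: int = 20_000
    frac_chimeric: float = 0.5
    frac_intramolecular_of_chimeric: float = 0.2
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    fragment_length_range: tuple[int, int] = (25, 60)
    replicate_count: int = 2
    seed: int = 0
    # genome layout
    gene_length_range: tuple[int, int] = (300, 900)
    srna_length_range: tuple[int, int] = (80, 200)
    min_gap: int = 30
    max_gap: int = 400
    frac_zero_gap: float = 0.1
    n_repeats: int = 0
    repeat_length: int = 60
    circular: bool = True
    chrom: str = "chr"

    def validate(self) -> None:
        if self.n_genes + self.n_srnas < 2:
            raise SimConfigError("need at least two features (n_genes + n_srnas >= 2)")
        for name in ("frac_chimeric", "frac_intramolecular_of_chimeric", "frac_zero_gap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.fragment_length_range[0] < 20:
            raise SimConfigError("fragment lengths must be >= 20 nt")
        if self.fragment_length_range[0] > self.fragment_length_range[1]:
            raise SimConfigError("fragment_length_range must be (lo, hi) with lo <= hi")
        for a, b, fold in self.planted_pairs:
            if fold < 1:
                raise SimConfigError(f"enrichment_fold must be >= 1 ({a},{b}: {fold})")
            if a == b:
                raise SimConfigError(f"planted pair must join two distinct features ({a})")


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """A single synthetic chromosome."""

    chrom: str
    seq: str
    circular: bool = True
    repeat_regions: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {self.chrom: self.length}

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """1-based inclusive subsequence, reverse-complemented for '-'."""
        s = self.seq[start - 1:end]
        return reverse_complement(s) if strand == "-" else s

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, self.length, 70):
                fh.write(self.seq[i:i + 70] + "\n")


def _generate_features(config: SimConfig, rng: np.random.Generator) -> FeatureTable:
    """Place non-overlapping gene/sRNA features along the chromosome.

    Intergenic gaps are either exactly 0 (adjacent features, exercising the
    junction-artifact class) or at least ``min_gap`` nt, so UA features tile
    the complement exactly at the default minimum UA length.
    """
    n = config.n_genes + config.n_srnas
    kinds = np.array(["gene"] * config.n_genes + ["srna"] * config.n_srnas)
    rng.shuffle(kinds)
    glo, ghi = config.gene_length_range
    slo, shi = config.srna_length_range
    lengths = np.where(
        kinds == "gene",
        rng.integers(glo, ghi + 1, size=n),
        rng.integers(slo, shi + 1, size=n),
    )
    total_len = int(lengths.sum())
    if total_len + (n + 1) * config.min_gap > config.genome_length:
        raise SimSizeError(
            f"{n} features of total length {total_len} nt do not fit in "
            f"{config.genome_length} nt with {config.min_gap} nt gaps"
        )
    # raw gaps: mixture of zero (adjacent) and uniform [min_gap, max_gap]
    raw = rng.integers(config.min_gap, config.max_gap + 1, size=n + 1).astype(float)
    zero = rng.random(n + 1) < config.frac_zero_gap
    zero[0] = zero[-1] = False  # keep UA margins at both chromosome ends
    raw[zero] = 0.0
    leftover = config.genome_length - total_len
    scale = leftover / raw.sum()
    gaps = np.where(raw > 0, np.maximum(config.min_gap, np.floor(raw * scale)), 0).astype(int)
    # never exceed the chromosome; surplus goes to the trailing UA region
    while total_len + gaps.sum() > config.genome_length:
        i = int(np.argmax(gaps))
        gaps[i] = max(config.min_gap, gaps[i] - (total_len + gaps.sum() - config.genome_length))
        if gaps.sum() + total_len > config.genome_length and gaps[i] == config.min_gap:
            raise SimSizeError("cannot satisfy gap constraints")  # pragma: no cover

    strands = rng.choice(["+", "-"], size=n)
    rows = []
    gene_i = srna_i = 0
    pos = 1
    for j in range(n):
        pos += gaps[j]
        start, end = pos, pos + int(lengths[j]) - 1
        if kinds[j] == "gene":
            gene_i += 1
            fid, ftype = f"gene{gene_i:03d}", "CDS"
        else:
            srna_i += 1
            fid, ftype = f"srna{srna_i:02d}", "sRNA"
        rows.append((fid, config.chrom, start, end, strands[j], ftype))
        pos = end + 1
    df = pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand", "ftype"])
    return FeatureTable(df)


def _unique_kmer_sequence(
    length: int,
    k: int,
    rng: np.random.Generator,
    exempt: tuple[tuple[int, int], ...] = (),
) -> str:
    """Random sequence whose canonical k-mers are unique outside *exempt*.

    Reverse-complement-palindromic k-mers are also eliminated so that every
    seed match identifies both a unique position and a unique strand.
    Works on 2-bit-encoded windows so each repair round is vectorised.
    """
    codes = rng.integers(0, 4, size=length)
    exempt_pos = np.zeros(length, dtype=bool)
    for s, e in exempt:
        exempt_pos[s - 1:e] = True
    # window i is checked unless it overlaps an exempt position
    csum = np.concatenate(([0], np.cumsum(exempt_pos)))
    checked = (csum[k:] - csum[:-k]) == 0
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    for _round in range(100):
        W = np.lib.stride_tricks.sliding_window_view(codes, k)
        fwd = W @ pw
        rev = (3 - W) @ pw[::-1]
        canon = np.minimum(fwd, rev)
        pal = (fwd == rev) & checked
        pos = np.flatnonzero(checked)
        order = pos[np.argsort(canon[pos], kind="mergesort")]
        dup = order[1:][canon[order[1:]] == canon[order[:-1]]]
        clashes = np.union1d(dup, np.flatnonzero(pal))
        if clashes.size == 0:
            return "".join("ACGT"[c] for c in codes)
        mid = np.unique(clashes + k // 2)
        codes[mid] = (codes[mid] + rng.integers(1, 4, size=mid.size)) % 4
    raise RuntimeError("could not build a unique-k-mer genome")  # pragma: no cover


def generate_features(config: SimConfig) -> FeatureTable:
    """The annotation half of :func:`generate_genome` (no sequence built)."""
    config.validate()
    return _generate_features(config, np.random.default_rng(config.seed))


def generate_genome(config: SimConfig) -> tuple[Genome, FeatureTable]:
    """Generate the synthetic chromosome and its feature annotation.

    Deterministic in ``config.seed``; raises :class:`SimSizeError` when the
    configured features cannot fit. Optional repeat regions are created by
    copying an intergenic window to a second intergenic location; both copies
    are flagged in ``Genome.repeat_regions``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    features = _generate_features(config, rng)

    repeats: list[tuple[int, int]] = []
    if config.n_repeats > 0:
        # place repeat copies in the widest intergenic gaps
        gaps = _intergenic_gaps(features, config.genome_length)
        gaps = [g for g in gaps if g[1] - g[0] + 1 >= config.repeat_length + 10]
        gaps.sort(key=lambda g: g[0] - g[1])  # widest first
        need = 2 * config.n_repeats
        if len(gaps) < need:
            raise SimSizeError("not enough intergenic space for repeat regions")
        for g in gaps[:need]:
            mid = (g[0] + g[1] - config.repeat_length) // 2
            repeats.append((mid, mid + config.repeat_length - 1))

    seq = _unique_kmer_sequence(config.genome_length, k=20, rng=rng,
                                exempt=tuple(repeats))
    if repeats:
        seq = list(seq)
        for a, b in zip(repeats[0::2], repeats[1::2]):
            seq[b[0] - 1:b[1]] = seq[a[0] - 1:a[1]]
        seq = "".join(seq)
    genome = Genome(config.chrom, seq, circular=config.circular,
                    repeat_regions=tuple(repeats))
    return genome, features


def _intergenic_gaps(features: FeatureTable, length: int) -> list[tuple[int, int]]:
    gaps, pos = [], 1
    for row in features.df.itertuples(index=False):
        if row.start > pos:
            gaps.append((pos, row.start - 1))
        pos = max(pos, row.end + 1)
    if pos <= length:
        gaps.append((pos, length))
    return gaps


# ---------------------------------------------------------------------------
# abundances and ligation events
# ---------------------------------------------------------------------------

def draw_abundances(features: FeatureTable, config: SimConfig,
                    rng: np.random.Generator | None = None) -> pd.Series:
    """Log-normal relative abundances per annotated (non-UA) feature.

    Heavy-tailed expression is what shapes the background ligation structure
    the enrichment test has to absorb; weights are normalised to sum to 1.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu, sigma = config.abundance_lognormal_mu_sigma
    ann = features.df[features.df["ftype"] != "UA"]
    w = rng.lognormal(mu, sigma, size=len(ann))
    return pd.Series(w / w.sum(), index=ann["id"].to_numpy())


def choose_planted_pairs(
    features: FeatureTable,
    abundances: pd.Series,
    n_pairs: int,
    enrichment_fold: float,
    rng: np.random.Generator,
    min_separation: int = 2000,
    srna_partner: bool = True,
) -> tuple[tuple[str, str, float], ...]:
    """Pick plantable feature pairs: expressed and distal.

    Candidates are drawn from features in the upper half of the abundance
    distribution, with edge separation beyond *min_separation* so the
    distance filter cannot erase the planted signal. When *srna_partner* is
    set, each pair includes at least one sRNA if any qualifies (mirroring
    sRNA-mRNA / sRNA-sRNA interactions).
    """
    df = features.df[features.df["ftype"] != "UA"]
    med = abundances.median()
    rich = df[df["id"].map(abundances) >= med]
    srnas = rich[rich["ftype"] == "sRNA"]["id"].tolist()
    others = rich["id"].tolist()
    span = df.set_index("id")
    pairs: list[tuple[str, str, float]] = []
    used: set[str] = set()
    attempts = 0
    while len(pairs) < n_pairs and attempts < 10_000:
        attempts += 1
        fresh_srnas = [s for s in srnas if s not in used]
        if srna_partner and fresh_srnas:
            a = fresh_srnas[int(rng.integers(len(fresh_srnas)))]
        else:
            a = others[int(rng.integers(len(others)))]
        b = others[int(rng.integers(len(others)))]
        if a == b or a in used or b in used:
            continue
        gap = _edge_gap(span.loc[a], span.loc[b])
        if gap <= min_separation:
            continue
        pairs.append((a, b, float(enrichment_fold)))
        used.update((a, b))
    if len(pairs) < n_pairs:
        raise SimConfigError("could not find enough distal expressed pairs to plant")
    return tuple(pairs)


def _edge_gap(fa, fb) -> int:
    if fa.start > fb.start:
        fa, fb = fb, fa
    return max(0, int(fb.start) - int(fa.end) - 1)


def _fragment_coords(
    starts: np.ndarray, ends: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform fragments within [start, end], clipped to the feature length."""
    flo, fhi = config.fragment_length_range
    feat_len = ends - starts + 1
    L = np.minimum(rng.integers(flo, fhi + 1, size=starts.size), feat_len)
    off = (rng.random(starts.size) * (feat_len - L + 1)).astype(int)
    s = starts + off
    return s, s + L - 1


def simulate_truth(
    config: SimConfig,
    features: FeatureTable,
    abundances: pd.Series,
    replicate: int = 1,
) -> pd.DataFrame:
    """One replicate's ligation events as a truth table (no sequences).

    The replicate stream is seeded with ``config.seed + replicate``
    (1-based index), so replicates are reproducibly independent. Chimeric
    background pairs (i, j) are drawn with probability proportional to
    ``a_i * a_j * e_ij`` where ``e_ij`` is the configured enrichment fold for
    planted pairs and 1 otherwise; fragment coordinates are uniform within
    the feature and fragment order within the read is randomised.
    """
    config.validate()
    if (abundances <= 0).any():
        raise SimConfigError("abundances must be strictly positive")
    rng = np.random.default_rng(config.seed + replicate)
    ann = features.df[features.df["ftype"] != "UA"].set_index("id")
    a = abundances.reindex(ann.index)
    if a.isna().any():
        raise SimConfigError("abundances missing for some features")

    flo, _ = config.fragment_length_range
    ok = ann["length"] >= flo
    if not ok.all():
        for fid in ann.index[~ok]:
            log.warning("feature %s shorter than minimum fragment length; skipped", fid)
        ann = ann[ok]
        a = a[ok]
    ids = ann.index.to_numpy()
    starts = ann["start"].to_numpy()
    ends = ann["end"].to_numpy()
    strands = ann["strand"].to_numpy()
    p = (a / a.sum()).to_numpy()

    n_chim = int(round(config.n_reads * config.frac_chimeric))
    n_intra = int(round(n_chim * config.frac_intramolecular_of_chimeric))
    n_pair = n_chim - n_intra
    n_non = config.n_reads - n_chim

    idx_of = {fid: i for i, fid in enumerate(ids)}
    for fa, fb, _fold in config.planted_pairs:
        if fa not in idx_of or fb not in idx_of:
            raise SimConfigError(f"planted pair references unknown feature: ({fa}, {fb})")

    parts = []

    def _single(n: int, cls: str, two_frags: bool) -> None:
        if n == 0:
            return
        fi = rng.choice(len(ids), size=n, p=p)
        s1, e1 = _fragment_coords(starts[fi], ends[fi], config, rng)
        rec = {
            "cls": cls,
            "feat1": ids[fi], "start1": s1, "end1": e1, "strand1": strands[fi],
        }
        if two_frags:
            s2, e2 = _fragment_coords(starts[fi], ends[fi], config, rng)
            rec.update({"feat2": ids[fi], "start2": s2, "end2": e2,
                        "strand2": strands[fi]})
        parts.append(pd.DataFrame(rec))

    _single(n_non, "non_chimeric", two_frags=False)
    _single(n_intra, "intramolecular", two_frags=True)

    if n_pair > 0:
        if len(ids) < 2:
            raise SimConfigError("need >= 2 features for intermolecular chimeras")
        iu, ju = np.triu_indices(len(ids), k=1)
        w = p[iu] * p[ju]
        planted_mask = np.zeros(w.size, dtype=bool)
        pair_pos = {(min(i, j), max(i, j)): t
                    for t, (i, j) in enumerate(zip(iu, ju))}
        for fa, fb, fold in config.planted_pairs:
            i, j = idx_of[fa], idx_of[fb]
            t = pair_pos[(min(i, j), max(i, j))]
            w[t] *= fold
            planted_mask[t] = True
        w = w / w.sum()
        draw = rng.choice(w.size, size=n_pair, p=w)
        fi, fj = iu[draw], ju[draw]
        s1, e1 = _fragment_coords(starts[fi], ends[fi], config, rng)
        s2, e2 = _fragment_coords(starts[fj], ends[fj], config, rng)
        cls = np.where(planted_mask[draw], "planted_pair", "background_pair")
        df = pd.DataFrame({
            "cls": cls,
            "feat1": ids[fi], "start1": s1, "end1": e1, "strand1": strands[fi],
            "feat2": ids[fj], "start2": s2, "end2": e2, "strand2": strands[fj],
        })
        # ligation orientation is unknowable: randomise fragment order
        flip = rng.random(len(df)) < 0.5
        for c1, c2 in (("feat1", "feat2"), ("start1", "start2"),
                       ("end1", "end2"), ("strand1", "strand2")):
            v1, v2 = df[c1].to_numpy().copy(), df[c2].to_numpy().copy()
            df.loc[flip, c1] = v2[flip]
            df.loc[flip, c2] = v1[flip]
        parts.append(df)

    truth = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=TRUTH_COLUMNS[2:])
    perm = rng.permutation(len(truth))
    truth = truth.iloc[perm].reset_index(drop=True)
    truth.insert(0, "read_id", [f"r{replicate}_{i:06d}" for i in range(len(truth))])
    truth.insert(1, "replicate", replicate)
    for col in ("feat2", "strand2"):
        if col not in truth.columns:
            truth[col] = pd.NA
    for col in ("start2", "end2"):
        if col not in truth.columns:
            truth[col] = np.nan
    return truth[TRUTH_COLUMNS]


def reads_from_truth(truth: pd.DataFrame, genome: Genome,
                     quality_char: str = "I") -> list:
    """Materialise FASTQ records (Biopython SeqRecords) from a truth table.

    The read sequence is fragment1 + fragment2 on each fragment's source
    strand; qualities are constant (unused downstream).
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    qual = ord(quality_char) - 33
    for row in truth.itertuples(index=False):
        s = genome.fetch(int(row.start1), int(row.end1), row.strand1)
        if isinstance(row.feat2, str):
            s += genome.fetch(int(row.start2), int(row.end2), row.strand2)
        rec = SeqRecord(Seq(s), id=row.read_id, description="")
        rec.letter_annotations["phred_quality"] = [qual] * len(s)
        records.append(rec)
    return records


def simulate_ligation(
    config: SimConfig,
    genome: Genome,
    features: FeatureTable,
    abundances: pd.Series | None = None,
) -> tuple[dict[int, list], pd.DataFrame]:
    """All replicates: FASTQ records per replicate plus the combined truth table."""
    if abundances is None:
        abundances = draw_abundances(features, config)
    reads: dict[int, list] = {}
    truths = []
    for rep in range(1, config.replicate_count + 1):
        truth = simulate_truth(config, features, abundances, replicate=rep)
        reads[rep] = reads_from_truth(truth, genome)
        truths.append(truth)
    return reads, pd.concat(truths, ignore_index=True)


def write_fastq(records, path) -> None:
    from Bio import SeqIO
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# truth-coordinate alignments and the toy aligner
# ---------------------------------------------------------------------------

def emit_truth_alignments(truth: pd.DataFrame, features: FeatureTable,
                          chrom: str | None = None) -> list:
    """Alignments placed exactly at truth coordinates (bypasses alignment).

    Used for exact end-to-end conservation tests. Raises ``ValueError`` when
    a truth row references an unknown feature or coordinates outside its
    bounds.
    """
    from .assign import ReadAlignment, Segment

    span = features.df.set_index("id")
    out = []
    for row in truth.itertuples(index=False):
        segs = []
        for feat, s, e, strand in (
            (row.feat1, row.start1, row.end1, row.strand1),
            (row.feat2, row.start2, row.end2, row.strand2),
        ):
            if not isinstance(feat, str):
                continue
            if feat not in span.index:
                raise ValueError(f"truth references unknown feature {feat!r}")
            f = span.loc[feat]
            s, e = int(s), int(e)
            if s < f.start or e > f.end:
                raise ValueError(
                    f"truth fragment {s}-{e} outside feature {feat} "
                    f"({f.start}-{f.end})")
            segs.append(Segment(chrom or f.chrom, s, e, strand, False))
        out.append(ReadAlignment(row.read_id, segs))
    return out


def truth_segments_frame(truth: pd.DataFrame, features: FeatureTable) -> pd.DataFrame:
    """Vectorised variant of :func:`emit_truth_alignments`: one row per segment."""
    span = features.df.set_index("id")
    frames = []
    for k in ("1", "2"):
        sub = truth[truth[f"feat{k}"].notna()]
        if sub.empty:
            continue
        feats = sub[f"feat{k}"]
        unknown = ~feats.isin(span.index)
        if unknown.any():
            raise ValueError(
                f"truth references unknown feature {feats[unknown].iloc[0]!r}")
        frames.append(pd.DataFrame({
            "read_id": sub["read_id"].to_numpy(),
            "chrom": span.loc[feats, "chrom"].to_numpy(),
            "start": sub[f"start{k}"].astype(int).to_numpy(),
            "end": sub[f"end{k}"].astype(int).to_numpy(),
            "strand": sub[f"strand{k}"].to_numpy(),
            "ambiguous": False,
        }))
    if not frames:
        return pd.DataFrame(
            columns=["read_id", "chrom", "start", "end", "strand", "ambiguous"])
    return pd.concat(frames, ignore_index=True)


class ToyAligner:
    """Exact-match split aligner over a unique-20-mer genome.

    For each read the longest exact-match prefix and suffix are located by a
    unique seed k-mer (both strands) and greedy extension. A read whose seed
    occurs at more than one genomic placement (repeat region) is flagged
    ambiguous; a read with no seed hit is left unmapped.
    """

    def __init__(self, genome: Genome, k: int = 20):
        self.genome = genome
        self.k = k
        idx: dict[str, list[int]] = {}
        seq = genome.seq
        for i in range(len(seq) - k + 1):
            idx.setdefault(seq[i:i + k], []).append(i)
        self._idx = idx

    def _candidates(self, seed: str) -> list[tuple[int, str]]:
        hits = [(p, "+") for p in self._idx.get(seed, ())]
        hits += [(p, "-") for p in self._idx.get(reverse_complement(seed), ())]
        return hits

    def _extend_prefix(self, read: str, pos: int, strand: str):
        """Longest match of a read prefix anchored at seed position *pos*."""
        g = self.genome.seq
        k = self.k
        if strand == "+":
            L = k
            while pos + L < len(g) and L < len(read) and read[L] == g[pos + L]:
                L += 1
            return (pos + 1, pos + L, "+", L)
        # '-': read prefix == revcomp(genome[lo:pos+k]); extend genome leftwards
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        L = k
        while pos - (L - k) - 1 >= 0 and L < len(read) and \
                read[L] == comp[g[pos - (L - k) - 1]]:
            L += 1
        lo = pos - (L - k)
        return (lo + 1, lo + k + (L - k), "-", L)

    def _extend_suffix(self, read: str, pos: int, strand: str):
        """Longest match of a read suffix whose last k-mer sits at *pos*."""
        g = self.genome.seq
        k = self.k
        if strand == "+":
            L = k
            while pos - (L - k) - 1 >= 0 and L < len(read) and \
                    read[-L - 1] == g[pos - (L - k) - 1]:
                L += 1
            lo = pos - (L - k)
            return (lo + 1, lo + L, "+", L)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        L = k
        while pos + L < len(g) and L < len(read) and \
                read[-L - 1] == comp[g[pos + L]]:
            L += 1
        return (pos + 1, pos + L, "-", L)

    def align(self, read_id: str, seq: str):
        from .assign import ReadAlignment, Segment

        chrom = self.genome.chrom
        if len(seq) < self.k:
            return ReadAlignment(read_id, [])
        pre_hits = self._candidates(seq[:self.k])
        suf_hits = self._candidates(seq[-self.k:])
        if len(pre_hits) > 1 or len(suf_hits) > 1:
            segs = []
            for hits, which in ((pre_hits, "pre"), (suf_hits, "suf")):
                if hits:
                    pos, strand = hits[0]
                    s, e, st, _L = (self._extend_prefix(seq, pos, strand)
                                    if which == "pre"
                                    else self._extend_suffix(seq, pos, strand))
                    segs.append(Segment(chrom, s, e, st, True))
            return ReadAlignment(read_id, segs)
        if not pre_hits and not suf_hits:
            return ReadAlignment(read_id, [])
        segs = []
        pre = suf = None
        if pre_hits:
            pos, strand = pre_hits[0]
            pre = self._extend_prefix(seq, pos, strand)
        if suf_hits:
            pos, strand = suf_hits[0]
            suf = self._extend_suffix(seq, pos, strand)
        if pre is not None:
            segs.append(Segment(chrom, pre[0], pre[1], pre[2], False))
            if pre[3] == len(seq):  # whole read in one block
                return ReadAlignment(read_id, segs)
        if suf is not None:
            same = pre is not None and (suf[0], suf[1], suf[2]) == tuple(pre[:3])
            if not same:
                segs.append(Segment(chrom, suf[0], suf[1], suf[2], False))
        return ReadAlignment(read_id, segs)


def toy_align(reads, genome: Genome, k: int = 20) -> list:
    """Align FASTQ records (SeqRecords or (id, seq) pairs) against *genome*."""
    aligner = ToyAligner(genome, k=k)
    out = []
    for rec in reads:
        if hasattr(rec, "seq"):
            rid, seq = rec.id, str(rec.seq)
        else:
            rid, seq = rec
        out.append(aligner.align(rid, seq))
    return out


def derive_replicate_config(config: SimConfig, replicate: int) -> SimConfig:
    """Convenience: a config whose base seed points at one replicate stream."""
    return replace(config, seed=config.seed + replicate, replicate_count=1)
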