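"""Chimeric read classification and interaction count matrices.

Each aligned read becomes exactly one :class:`ChimeraCall`:

``interaction``
    two fragments in distinct features separated by more than the distance
    threshold (default 2000 bp, closest edges);
``intramolecular``
    both fragments within one feature (counted toward expression, not
    interaction);
``junction_artifact``
    fragments in adjacent/overlapping features (edge gap <= 50 nt), the
    signature of a non-chimeric read spanning a boundary;
``proximal_excluded``
    distinct features closer than the distance threshold;
``repeat_ambiguous``
    any fragment with an ambiguous placement (repetitive region);
``unassigned``
    unmapped reads, reads whose fragment overlaps no feature, and
    single-fragment (non-chimeric) reads.

Interaction-class calls accumulate into a symmetric pair-count matrix with
per-feature marginals, which is what the hypergeometric enrichment test
consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .features import FeatureTable

log = logging.getLogger(__name__)

CALL_CLASSES = (
    "interaction", "intramolecular", "junction_artifact",
    "proximal_excluded", "repeat_ambiguous", "unassigned",
)

DEFAULT_DISTANCE_THRESHOLD = 2000
DEFAULT_JUNCTION_GAP = 50


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    is_ambiguous: bool = False


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    segments: list[Segment] = field(default_factory=list)


@dataclass(frozen=True)
class ChimeraCall:
    read_id: str
    featureA: str | None
    featureB: str | None  # None for single-feature reads
    cls: str


class FeatureUniverseError(ValueError):
    """Matrices over different feature universes cannot be merged."""


# ---------------------------------------------------------------------------
# segment -> feature assignment
# ---------------------------------------------------------------------------

class _ChromIndex:
    """Per-chromosome arrays for overlap queries."""

    def __init__(self, df: pd.DataFrame):
        self.starts = df["start"].to_numpy()
        self.ends = df["end"].to_numpy()
        self.lengths = df["length"].to_numpy()
        self.ids = df["id"].to_numpy()
        # fast path is valid only when features do not overlap
        self.disjoint = bool((self.starts[1:] > self.ends[:-1]).all()) \
            if len(df) > 1 else True

    def best_feature(self, start: int, end: int) -> str | None:
        """Maximal-overlap feature; ties broken by smaller feature then id."""
        ov = np.minimum(self.ends, end) - np.maximum(self.starts, start) + 1
        mask = ov > 0
        if not mask.any():
            return None
        cand = np.flatnonzero(mask)
        key = sorted(cand, key=lambda i: (-ov[i], self.lengths[i], self.ids[i]))
        return self.ids[key[0]]


def _build_index(features: FeatureTable) -> dict[str, _ChromIndex]:
    return {c: _ChromIndex(g) for c, g in features.df.groupby("chrom")}


def _feature_gap(fa, fb, circular: bool, chrom_len: int | None) -> int:
    """Closest-edge separation (nt) between two features; 0 when overlapping.

    On a circular chromosome the wrap-around gap is also considered.
    """
    if fa["chrom"] != fb["chrom"]:
        return int(1e12)
    if fa["start"] > fb["start"]:
        fa, fb = fb, fa
    linear = max(0, int(fb["start"]) - int(fa["end"]) - 1)
    if circular and chrom_len:
        wrap = max(0, chrom_len - int(fb["end"]) + int(fa["start"]) - 1)
        return min(linear, wrap)
    return linear


def _classify_pair(fid1: str, fid2: str, gap: int,
                   distance_threshold: int, junction_gap: int) -> str:
    if fid1 == fid2:
        return "intramolecular"
    if gap <= junction_gap:
        return "junction_artifact"
    if gap <= distance_threshold:
        return "proximal_excluded"
    return "interaction"


def assign_read(
    aln: ReadAlignment,
    features: FeatureTable,
    distance_threshold: int = DEFAULT_DISTANCE_THRESHOLD,
    junction_gap: int = DEFAULT_JUNCTION_GAP,
    circular: bool = False,
    chrom_lengths: dict[str, int] | None = None,
    _index: dict[str, _ChromIndex] | None = None,
) -> ChimeraCall:
    """Classify one aligned read against the feature universe.

    Strand is ignored in overlap assignment (the recovered orientation of a
    psoralen chimera is not informative); each segment goes to the feature
    with maximal overlap, ties to the smaller feature then lexicographic id.
    """
    idx = _index if _index is not None else _build_index(features)
    segs = aln.segments
    if any(s.is_ambiguous for s in segs):
        return ChimeraCall(aln.read_id, None, None, "repeat_ambiguous")
    if len(segs) == 0:
        return ChimeraCall(aln.read_id, None, None, "unassigned")
    if len(segs) > 2:
        log.warning("read %s has %d segments; left unassigned", aln.read_id, len(segs))
        return ChimeraCall(aln.read_id, None, None, "unassigned")
    fids = []
    for s in segs:
        if s.chrom not in idx:
            raise ValueError(f"segment on unknown chromosome {s.chrom!r}")
        fids.append(idx[s.chrom].best_feature(s.start, s.end))
    if any(f is None for f in fids):
        return ChimeraCall(aln.read_id, fids[0], None, "unassigned")
    if len(fids) == 1:
        return ChimeraCall(aln.read_id, fids[0], None, "unassigned")
    f1, f2 = fids
    span = features._by_id
    chrom = span.loc[f1, "chrom"]
    clen = (chrom_lengths or {}).get(chrom)
    gap = _feature_gap(span.loc[f1], span.loc[f2], circular, clen)
    cls = _classify_pair(f1, f2, gap, distance_threshold, junction_gap)
    if cls == "intramolecular":
        return ChimeraCall(aln.read_id, f1, f1, cls)
    a, b = sorted((f1, f2))
    return ChimeraCall(aln.read_id, a, b, cls)


def assign_reads(
    alignments,
    features: FeatureTable,
    distance_threshold: int = DEFAULT_DISTANCE_THRESHOLD,
    junction_gap: int = DEFAULT_JUNCTION_GAP,
    circular: bool = False,
    chrom_lengths: dict[str, int] | None = None,
) -> list[ChimeraCall]:
    idx = _build_index(features)
    return [
        assign_read(a, features, distance_threshold, junction_gap,
                    circular, chrom_lengths, _index=idx)
        for a in alignments
    ]


def assign_frame(
    segments: pd.DataFrame,
    features: FeatureTable,
    distance_threshold: int = DEFAULT_DISTANCE_THRESHOLD,
    junction_gap: int = DEFAULT_JUNCTION_GAP,
    circular: bool = False,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Vectorised assignment over a segment table.

    *segments* columns: ``read_id, chrom, start, end, strand, ambiguous``.
    Segments fully contained in a feature are resolved with a sorted-array
    lookup (valid because features are disjoint per chromosome); anything
    irregular falls back to the per-read path. Returns one row per read with
    columns ``read_id, featureA, featureB, cls`` and is equivalent to
    :func:`assign_read` applied read by read.
    """
    if segments.empty:
        return pd.DataFrame(columns=["read_id", "featureA", "featureB", "cls"])
    idx = _build_index(features)
    seg = segments.reset_index(drop=True)
    fid = np.full(len(seg), None, dtype=object)
    resolved = np.zeros(len(seg), dtype=bool)
    for chrom, grp in seg.groupby("chrom"):
        if chrom not in idx:
            raise ValueError(f"segment on unknown chromosome {chrom!r}")
        ci = idx[chrom]
        rows = grp.index.to_numpy()
        if ci.disjoint and len(ci.starts):
            pos = np.searchsorted(ci.starts, grp["start"].to_numpy(), side="right") - 1
            ok = pos >= 0
            contained = np.zeros(len(grp), dtype=bool)
            contained[ok] = (grp["start"].to_numpy()[ok] >= ci.starts[pos[ok]]) & \
                            (grp["end"].to_numpy()[ok] <= ci.ends[pos[ok]])
            fid[rows[contained]] = ci.ids[pos[contained]]
            resolved[rows[contained]] = True
    # fallback: maximal-overlap scan for uncontained segments
    for i in np.flatnonzero(~resolved):
        row = seg.iloc[i]
        fid[i] = idx[row["chrom"]].best_feature(int(row["start"]), int(row["end"]))

    seg = seg.assign(_fid=fid)
    span = features._by_id
    f_start = span["start"].to_dict()
    f_end = span["end"].to_dict()
    f_chrom = span["chrom"].to_dict()

    order = seg.sort_values("read_id", kind="mergesort").reset_index(drop=True)
    rid = order["read_id"].to_numpy()
    uniq, first, counts = np.unique(rid, return_index=True, return_counts=True)

    out_rows = []
    two = counts == 2
    one = counts == 1
    # two-segment reads, all unambiguous and assigned: vectorised classify
    amb = order["ambiguous"].to_numpy()
    fids = order["_fid"].to_numpy()
    for u, f0, c in zip(uniq[~(two | one)], first[~(two | one)], counts[~(two | one)]):
        out_rows.append((u, None, None, "unassigned"))
        if c > 2:
            log.warning("read %s has %d segments; left unassigned", u, c)
    for u, f0 in zip(uniq[one], first[one]):
        if amb[f0]:
            out_rows.append((u, None, None, "repeat_ambiguous"))
        else:
            out_rows.append((u, fids[f0], None, "unassigned"))
    i2 = first[two]
    if i2.size:
        a1, a2 = fids[i2], fids[i2 + 1]
        amb2 = amb[i2] | amb[i2 + 1]
        for u, f1, f2, am in zip(uniq[two], a1, a2, amb2):
            if am:
                out_rows.append((u, None, None, "repeat_ambiguous"))
                continue
            if f1 is None or f2 is None:
                out_rows.append((u, f1 if f1 is not None else f2, None, "unassigned"))
                continue
            if f1 == f2:
                out_rows.append((u, f1, f1, "intramolecular"))
                continue
            c1 = f_chrom[f1]
            if c1 != f_chrom[f2]:
                gap = int(1e12)
            else:
                s1, e1 = f_start[f1], f_end[f1]
                s2, e2 = f_start[f2], f_end[f2]
                if s1 > s2:
                    s1, e1, s2, e2 = s2, e2, s1, e1
                gap = max(0, s2 - e1 - 1)
                clen = (chrom_lengths or {}).get(c1)
                if circular and clen:
                    gap = min(gap, max(0, clen - e2 + s1 - 1))
            cls = _classify_pair(f1, f2, gap, distance_threshold, junction_gap)
            fa, fb = (f1, f1) if cls == "intramolecular" else tuple(sorted((f1, f2)))
            out_rows.append((u, fa, fb, cls))
    out = pd.DataFrame(out_rows, columns=["read_id", "featureA", "featureB", "cls"])
    return out.sort_values("read_id", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------

def write_sam(alignments, chrom_lengths: dict[str, int], path) -> None:
    """Write alignments as SAM; supplementary segments get flag 0x800.

    Ambiguous segments are written with MAPQ 0, unambiguous with MAPQ 60;
    sequences are omitted ('*').
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            if not aln.segments:
                rec = pysam.AlignedSegment(fh.header)
                rec.query_name = aln.read_id
                rec.flag = 4
                fh.write(rec)
                continue
            for j, seg in enumerate(aln.segments):
                rec = pysam.AlignedSegment(fh.header)
                rec.query_name = aln.read_id
                rec.reference_id = tid[seg.chrom]
                rec.reference_start = seg.start - 1
                rec.mapping_quality = 0 if seg.is_ambiguous else 60
                rec.cigartuples = [(0, seg.end - seg.start + 1)]
                flag = 0
                if seg.strand == "-":
                    flag |= 16
                if j > 0:
                    flag |= 2048
                rec.flag = flag
                fh.write(rec)


def read_sam(path) -> list[ReadAlignment]:
    """Read a SAM file into alignments, grouping records by read name."""
    grouped: dict[str, list[Segment]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.query_name not in grouped:
                grouped[rec.query_name] = []
                order.append(rec.query_name)
            if rec.is_unmapped:
                continue
            grouped[rec.query_name].append(Segment(
                rec.reference_name,
                rec.reference_start + 1,
                rec.reference_end,
                "-" if rec.is_reverse else "+",
                rec.mapping_quality == 0,
            ))
    return [ReadAlignment(name, grouped[name]) for name in order]


def sam_chrom_lengths(path) -> dict[str, int]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return {sq["SN"]: sq["LN"] for sq in fh.header.to_dict().get("SQ", [])}


# ---------------------------------------------------------------------------
# interaction matrices
# ---------------------------------------------------------------------------

@dataclass
class InteractionMatrix:
    """Symmetric pair -> count table with per-feature marginals.

    ``pair_counts`` holds one row per canonically ordered feature pair
    (featureA <= featureB) with its interaction-class read count; N is the
    total inter-feature count; K_f the marginal count of feature f over all
    pairs containing it. Intramolecular counts are stored separately: they
    contribute to expression estimates, never to N.
    """

    pair_counts: pd.DataFrame  # columns featureA, featureB, count
    intramolecular: pd.Series = field(
        default_factory=lambda: pd.Series(dtype=int))
    feature_ids: frozenset[str] | None = None
    label: str = ""

    def __post_init__(self):
        pc = self.pair_counts
        if len(pc) and (pc["featureA"] > pc["featureB"]).any():
            raise ValueError("pair_counts must be canonically ordered (A <= B)")
        if len(pc) and (pc["featureA"] == pc["featureB"]).any():
            raise ValueError("self-pairs belong in intramolecular, not pair_counts")

    @property
    def N(self) -> int:
        return int(self.pair_counts["count"].sum()) if len(self.pair_counts) else 0

    def marginals(self) -> pd.Series:
        """K_f: total interaction count involving each feature."""
        if not len(self.pair_counts):
            return pd.Series(dtype=int)
        a = self.pair_counts.groupby("featureA")["count"].sum()
        b = self.pair_counts.groupby("featureB")["count"].sum()
        return a.add(b, fill_value=0).astype(int)

    def to_tsv(self, path) -> None:
        df = self.pair_counts.copy()
        K = self.marginals()
        df["K_A"] = df["featureA"].map(K).astype(int)
        df["K_B"] = df["featureB"].map(K).astype(int)
        df["N"] = self.N
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df[["featureA", "featureB", "count"]], label=label)


def build_interaction_matrix(calls, features: FeatureTable | None = None,
                             label: str = "") -> InteractionMatrix:
    """Count interaction-class calls into a matrix; order-invariant.

    *calls* may be a list of :class:`ChimeraCall` or a DataFrame with
    columns ``featureA, featureB, cls``.
    """
    if isinstance(calls, pd.DataFrame):
        df = calls
    else:
        df = pd.DataFrame(
            [(c.read_id, c.featureA, c.featureB, c.cls) for c in calls],
            columns=["read_id", "featureA", "featureB", "cls"],
        )
    inter = df[df["cls"] == "interaction"]
    if len(inter):
        a = np.minimum(inter["featureA"].to_numpy(), inter["featureB"].to_numpy())
        b = np.maximum(inter["featureA"].to_numpy(), inter["featureB"].to_numpy())
        pc = (pd.DataFrame({"featureA": a, "featureB": b})
              .groupby(["featureA", "featureB"]).size()
              .rename("count").reset_index())
    else:
        pc = pd.DataFrame(columns=["featureA", "featureB", "count"])
    intra = df[df["cls"] == "intramolecular"].groupby("featureA").size().astype(int)
    universe = frozenset(features.ids) if features is not None else None
    return InteractionMatrix(pc, intramolecular=intra,
                             feature_ids=universe, label=label)


def merge_replicates(matrices: list[InteractionMatrix],
                     label: str = "merged") -> InteractionMatrix:
    """Element-wise sum of replicate matrices (marginals/N recomputed)."""
    if not matrices:
        raise ValueError("no matrices to merge")
    universes = [m.feature_ids for m in matrices if m.feature_ids is not None]
    if universes and any(u != universes[0] for u in universes):
        raise FeatureUniverseError("matrices cover different feature universes")
    pc = pd.concat([m.pair_counts for m in matrices], ignore_index=True)
    if len(pc):
        pc = pc.groupby(["featureA", "featureB"])["count"].sum().reset_index()
    intra = pd.concat([m.intramolecular for m in matrices])
    intra = intra.groupby(level=0).sum().astype(int) if len(intra) else intra
    return InteractionMatrix(pc, intramolecular=intra,
                             feature_ids=universes[0] if universes else None,
                             label=label)


def write_calls(calls, path) -> None:
    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame(
            [(c.read_id, c.featureA, c.featureB, c.cls) for c in calls],
            columns=["read_id", "featureA", "featureB", "cls"],
        )
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def class_tally(calls) -> dict[str, int]:
    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame([(c.cls,) for c in calls], columns=["cls"])
    t = calls["cls"].value_counts().to_dict()
    return {c: int(t.get(c, 0)) for c in CALL_CLASSES}
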