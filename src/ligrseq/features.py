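"""Genomic feature tables: annotation I/O and unannotated-region (UA) tiling.

A :class:`FeatureTable` is the feature universe every chimeric fragment is
assigned to: annotated transcripts (CDS, UTRs, sRNAs, stable RNAs) plus
auto-generated ``UA-start-stop`` features covering the unannotated complement
of the chromosome, so that fragments falling outside the annotation remain
assignable. Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import gffutils
import pandas as pd

log = logging.getLogger(__name__)

#: allowed feature classes
FEATURE_TYPES = ("CDS", "5UTR", "3UTR", "sRNA", "rRNA", "tRNA", "other_ncRNA", "UA")

_SO_TO_FTYPE = {
    "CDS": "CDS",
    "five_prime_UTR": "5UTR",
    "three_prime_UTR": "3UTR",
    "5UTR": "5UTR",
    "3UTR": "3UTR",
    "sRNA": "sRNA",
    "ncRNA": "other_ncRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "UA": "UA",
}

_FTYPE_TO_SO = {
    "CDS": "CDS",
    "5UTR": "five_prime_UTR",
    "3UTR": "three_prime_UTR",
    "sRNA": "sRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "other_ncRNA": "ncRNA",
    "UA": "UA",
}

_COLUMNS = ["id", "chrom", "start", "end", "strand", "ftype", "length"]


class AnnotationError(ValueError):
    """Raised for invalid or inconsistent annotation input."""


class FeatureTable:
    """Immutable-ish table of genomic features.

    Parameters
    ----------
    df:
        DataFrame with columns ``id, chrom, start, end, strand, ftype``
        (``length`` is recomputed). Features are stored sorted by
        ``(chrom, start, end, id)``.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in _COLUMNS[:-1] if c not in df.columns]
        if missing:
            raise AnnotationError(f"feature table missing columns: {missing}")
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["length"] = df["end"] - df["start"] + 1
        if (df["start"] > df["end"]).any():
            raise AnnotationError("feature with start > end")
        if (df["start"] < 1).any():
            raise AnnotationError("coordinates are 1-based; start < 1")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise AnnotationError(f"duplicate feature ids: {dups[:5]}")
        bad = ~df["ftype"].isin(FEATURE_TYPES)
        if bad.any():
            raise AnnotationError(
                f"unknown ftype values: {sorted(df.loc[bad, 'ftype'].unique())}"
            )
        ua = df["ftype"] == "UA"
        if (df.loc[ua, "strand"] != ".").any():
            raise AnnotationError("UA features must be unstranded ('.')")
        df = df.sort_values(["chrom", "start", "end", "id"], kind="mergesort")
        self.df = df.reset_index(drop=True)[_COLUMNS]
        self._by_id = self.df.set_index("id", drop=False)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, fid: str) -> bool:
        return fid in self._by_id.index

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.df.equals(other.df)

    def __repr__(self) -> str:
        n_ua = int((self.df["ftype"] == "UA").sum())
        return f"FeatureTable({len(self)} features, {n_ua} UA)"

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    def feature(self, fid: str):
        """Return the row for *fid* as a named tuple."""
        try:
            row = self._by_id.loc[fid]
        except KeyError:
            raise KeyError(f"unknown feature id: {fid!r}") from None
        return next(row.to_frame().T.itertuples(index=False))

    def annotated(self) -> "FeatureTable":
        """Subset without UA features."""
        return FeatureTable(self.df[self.df["ftype"] != "UA"])

    def subset(self, ids: Iterable[str]) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(self.df[self.df["id"].isin(ids)])

    # -- GFF3 I/O -----------------------------------------------------------
    def to_gff3(self, path) -> None:
        """Write the table as GFF3 (``ID=`` attribute carries the feature id)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in self.df.itertuples(index=False):
                so = _FTYPE_TO_SO[row.ftype]
                fh.write(
                    f"{row.chrom}\tligrseq\t{so}\t{row.start}\t{row.end}\t.\t"
                    f"{row.strand}\t.\tID={row.id}\n"
                )


def load_annotation(gff) -> FeatureTable:
    """Parse a GFF3 file (path or file-like) into a :class:`FeatureTable`.

    UTR rows are retained as distinct features; feature types outside the
    recognised set are mapped to ``other_ncRNA`` with a logged warning.
    Duplicate ``ID`` attributes raise :class:`AnnotationError`.
    """
    if hasattr(gff, "read"):
        data = gff.read()
    else:
        with open(gff) as fh:
            data = fh.read()
    body = [l for l in data.splitlines() if l.strip() and not l.startswith("#")]
    if not body:
        return FeatureTable(pd.DataFrame(columns=_COLUMNS[:-1]))
    try:
        db = gffutils.create_db(
            data,
            dbfn=":memory:",
            from_string=True,
            id_spec="ID",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises ValueError on duplicate IDs
        raise AnnotationError(f"failed to parse GFF3: {exc}") from exc

    records = []
    for feat in db.all_features():
        ftype = _SO_TO_FTYPE.get(feat.featuretype)
        if ftype is None:
            log.warning(
                "feature %s: unknown type %r mapped to other_ncRNA",
                feat.id, feat.featuretype,
            )
            ftype = "other_ncRNA"
        strand = feat.strand if feat.strand in ("+", "-") else "."
        if ftype == "UA":
            strand = "."
        records.append((feat.id, feat.seqid, feat.start, feat.end, strand, ftype))
    df = pd.DataFrame(records, columns=_COLUMNS[:-1])
    if df.empty:
        df = pd.DataFrame(columns=_COLUMNS[:-1])
    return FeatureTable(df)


def merged_intervals(df: pd.DataFrame) -> list[tuple[int, int]]:
    """Union of (start, end) intervals of *df* rows, sorted and merged."""
    ivs = sorted(zip(df["start"], df["end"]))
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def make_ua_features(
    features: FeatureTable,
    chrom_lengths: Mapping[str, int],
    min_ua_length: int = 30,
) -> FeatureTable:
    """Append UA features tiling the unannotated complement of each chromosome.

    Complement intervals of the annotated union that are at least
    *min_ua_length* long are added as features named ``UA-<start>-<stop>``
    (prefixed with the chromosome name when more than one chromosome is
    present), with strand ``.`` and ftype ``UA``.
    """
    for chrom in features.df["chrom"].unique():
        if chrom not in chrom_lengths:
            raise AnnotationError(f"no length given for chromosome {chrom!r}")
    multi = len(chrom_lengths) > 1
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = features.df[features.df["chrom"] == chrom]
        gaps = []
        pos = 1
        for s, e in merged_intervals(sub):
            if s > pos:
                gaps.append((pos, s - 1))
            pos = max(pos, e + 1)
        if pos <= length:
            gaps.append((pos, length))
        for s, e in gaps:
            if e - s + 1 < min_ua_length:
                continue
            name = f"UA-{chrom}-{s}-{e}" if multi else f"UA-{s}-{e}"
            rows.append((name, chrom, s, e, ".", "UA"))
    if not rows:
        return FeatureTable(features.df)
    ua = pd.DataFrame(rows, columns=_COLUMNS[:-1])
    return FeatureTable(pd.concat([features.df[_COLUMNS[:-1]], ua], ignore_index=True))
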