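"""Plate-reader promoter activity and competition-assay fitness statistics.

Promoter activity is the per-interval gain in background-subtracted GFP
fluorescence normalised by culture density, a_t = (GFP_t - GFP_{t-1}) /
OD600_t, smoothed with a centred 3-point moving average. Competition
fitness compares per-replicate CFU ratios (mutant/reference, normalised by
the verified inoculum ratio) between two assays with Welch's unequal
variance t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)


class ReporterInputError(ValueError):
    pass


@dataclass(frozen=True)
class ReporterSeries:
    times: np.ndarray
    od600: np.ndarray
    gfp: np.ndarray
    background_gfp: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        g = np.asarray(self.gfp, dtype=float)
        bg = (np.asarray(self.background_gfp, dtype=float)
              if self.background_gfp is not None else None)
        if not (t.size == od.size == g.size):
            raise ReporterInputError("times, od600 and gfp must have equal length")
        if bg is not None and bg.size != t.size:
            raise ReporterInputError("background series length mismatch")
        if t.size < 2:
            raise ReporterInputError("need at least 2 time points")
        if (np.diff(t) <= 0).any():
            raise ReporterInputError("times must be strictly increasing")
        if (od <= 0).any():
            raise ReporterInputError("OD600 must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od600", od)
        object.__setattr__(self, "gfp", g)
        object.__setattr__(self, "background_gfp", bg)


def promoter_activity(series: ReporterSeries, smooth_window: int = 3
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtracted per-interval promoter activity (AU).

    Returns ``(times[1:], activity)``; the moving average is centred and the
    window shrinks at the edges. Background is subtracted time-matched and
    negative fluorescence after subtraction is floored at 0 with a warning.
    """
    g = series.gfp.copy()
    if series.background_gfp is not None:
        g = g - series.background_gfp
        if (g < 0).any():
            log.warning("negative background-subtracted GFP floored at 0")
            g = np.maximum(g, 0.0)
    a = np.diff(g) / series.od600[1:]
    if smooth_window > 1:
        import pandas as pd
        a = (pd.Series(a)
             .rolling(smooth_window, center=True, min_periods=1)
             .mean().to_numpy())
    return series.times[1:], a


@dataclass(frozen=True)
class CompetitionAssay:
    """24 h CFU counts of the two co-cultured strains, per replicate."""

    cfu_strainA: np.ndarray
    cfu_strainB: np.ndarray
    inoculum_ratio: float = 1.0  # verified A:B starting ratio

    def __post_init__(self):
        a = np.asarray(self.cfu_strainA, dtype=float)
        b = np.asarray(self.cfu_strainB, dtype=float)
        if a.size != b.size:
            raise ReporterInputError("CFU arrays must have equal length")
        if a.size < 2:
            raise ReporterInputError("need >= 2 replicates per group")
        if (a < 0).any() or (b < 0).any():
            raise ReporterInputError("CFU counts must be non-negative")
        if (b == 0).any():
            raise ReporterInputError("zero denominator CFU")
        if self.inoculum_ratio <= 0:
            raise ReporterInputError("inoculum_ratio must be positive")
        object.__setattr__(self, "cfu_strainA", a)
        object.__setattr__(self, "cfu_strainB", b)

    @property
    def ratios(self) -> np.ndarray:
        return (self.cfu_strainA / self.cfu_strainB) / self.inoculum_ratio


class CompetitionResult(NamedTuple):
    ratios: np.ndarray
    ratios_reference: np.ndarray
    t_statistic: float
    p_value: float


def competition_fitness(assay: CompetitionAssay,
                        reference: CompetitionAssay,
                        log_ratios: bool = False) -> CompetitionResult:
    """Welch's unequal-variance t-test of CFU ratios between two assays.

    Satterthwaite degrees of freedom; two-sided P. ``log_ratios`` tests
    log2-transformed ratios instead of the untransformed default.
    """
    x = assay.ratios
    y = reference.ratios
    if log_ratios:
        x, y = np.log2(x), np.log2(y)
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return CompetitionResult(assay.ratios, reference.ratios, float(t), float(p))
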