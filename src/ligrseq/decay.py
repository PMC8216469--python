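"""Quantitative northern-blot computations.

Rifampicin-chase band intensities are normalised to a loading control
(16S/5S rRNA) and expressed as percent of the t=0 value; half-lives come
from an ordinary least-squares line on log10(percent remaining) versus
time, with t1/2 = -log10(2)/slope. Decay that is visibly two-phased is
handled by a two-segment fit whose breakpoint is chosen over the interior
sample times by total SSE and accepted when it lowers the BIC; the reported
half-life is always taken from the initial (first-segment) slope. Non
decaying series are censored as ">t_max".

Gel sizing and absolute quantification use plain standard curves:
log10(size) vs migration distance for ladders, intensity vs fmol for in
vitro transcribed standards (inverse regression), interpolation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

LOG10_2 = math.log10(2.0)


class DecayInputError(ValueError):
    pass


class FitError(ValueError):
    pass


class RangeError(ValueError):
    """Requested point lies outside the fitted standard-curve range."""


@dataclass(frozen=True)
class DecaySeries:
    """Loading-control-normalised decay time course.

    times are minutes after rifampicin addition (first point 0);
    percent_remaining is 100 at t=0 by construction.
    """

    times: np.ndarray
    percent_remaining: np.ndarray
    band: np.ndarray | None = None
    control: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.percent_remaining, dtype=float)
        if t.size != p.size:
            raise DecayInputError("times and percent_remaining differ in length")
        if t.size == 0 or t[0] != 0:
            raise DecayInputError("first time point must be 0")
        if (np.diff(t) <= 0).any():
            raise DecayInputError("times must be strictly increasing")
        if not np.isclose(p[0], 100.0):
            raise DecayInputError("percent_remaining must start at 100")
        if (p <= 0).any():
            raise DecayInputError("percent_remaining must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "percent_remaining", p)


def normalize_decay(times, band, control) -> DecaySeries:
    """percent_t = 100 * (band_t/control_t) / (band_0/control_0)."""
    t = np.asarray(times, dtype=float)
    b = np.asarray(band, dtype=float)
    c = np.asarray(control, dtype=float)
    if not (t.size == b.size == c.size):
        raise DecayInputError("times, band and control must have equal length")
    if (b <= 0).any() or (c <= 0).any():
        raise DecayInputError("band and control intensities must be positive")
    ratio = b / c
    pct = 100.0 * ratio / ratio[0]
    return DecaySeries(t, pct, band=b, control=c)


def average_replicates(series: list[DecaySeries]) -> DecaySeries:
    """Average replicate curves on the percent scale before fitting."""
    if not series:
        raise DecayInputError("no series to average")
    t0 = series[0].times
    for s in series[1:]:
        if not np.array_equal(s.times, t0):
            raise DecayInputError("replicates sampled at different times")
    pct = np.mean([s.percent_remaining for s in series], axis=0)
    return DecaySeries(t0, pct)


@dataclass(frozen=True)
class HalfLifeFit:
    """log10-linear decay fit; t_half = -log10(2)/slope from segment 1."""

    slope: float                 # log10(percent) per minute
    intercept: float
    t_half: float | None         # minutes; None when censored
    censored: bool
    t_max: float
    model: str                   # 'monophasic' | 'biphasic'
    breakpoint: float | None = None
    r_squared: float = float("nan")

    @property
    def label(self) -> str:
        if self.censored:
            return f">{self.t_max:g} min"
        return f"{self.t_half:.1f} min"


def _ols(t: np.ndarray, y: np.ndarray):
    res = sps.linregress(t, y)
    sse = float(np.sum((y - (res.intercept + res.slope * t)) ** 2))
    return res.slope, res.intercept, sse, res.rvalue ** 2


def _bic(sse: float, n_obs: int, n_par: int) -> float:
    sse = max(sse, 1e-30)  # exact fits: keep log finite, mono still wins on k
    return n_obs * math.log(sse / n_obs) + n_par * math.log(n_obs)


def fit_halflife(series: DecaySeries, model: str = "auto",
                 t_max: float | None = None) -> HalfLifeFit:
    """Fit a half-life to a normalised decay series.

    model='auto' compares the single line against the best two-segment fit
    (breakpoint on interior grid points, >= 3 points per segment, segments
    sharing the breakpoint sample) by BIC. A non-negative first-segment
    slope, or an implied half-life beyond *t_max* (default: the last sampled
    time), is reported censored as ">t_max".
    """
    if model not in ("auto", "mono", "biphasic"):
        raise ValueError(f"unknown model {model!r}")
    t = series.times
    y = np.log10(series.percent_remaining)
    n = t.size
    if n < 3:
        raise FitError("need at least 3 time points")
    if t_max is None:
        t_max = float(t[-1])

    slope_m, int_m, sse_m, r2_m = _ols(t, y)
    chosen = ("monophasic", slope_m, int_m, r2_m, None)

    if model in ("auto", "biphasic"):
        if n >= 6:
            best = None
            for i in range(2, n - 2):  # breakpoint index: >=3 points each side
                s1, i1, e1, _ = _ols(t[:i + 1], y[:i + 1])
                s2, i2, e2, _ = _ols(t[i:], y[i:])
                sse = e1 + e2
                if best is None or sse < best[0]:
                    best = (sse, i, s1, i1)
            sse_b, bi, s1, i1 = best
            take_biphasic = (model == "biphasic" or
                             _bic(sse_b, n, 5) < _bic(sse_m, n, 2))
            if take_biphasic:
                tss = float(np.sum((y - y.mean()) ** 2))
                r2_b = 1.0 - sse_b / tss if tss > 0 else 1.0
                chosen = ("biphasic", s1, i1, r2_b, float(t[bi]))
        elif model == "biphasic":
            raise FitError("biphasic fit needs >= 6 points (>= 3 per segment)")

    name, slope, intercept, r2, brk = chosen
    if slope >= 0:
        return HalfLifeFit(slope, intercept, None, True, t_max, name, brk, r2)
    t_half = -LOG10_2 / slope
    if t_half > t_max:
        return HalfLifeFit(slope, intercept, None, True, t_max, name, brk, r2)
    return HalfLifeFit(slope, intercept, t_half, False, t_max, name, brk, r2)


# ---------------------------------------------------------------------------
# standard curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """OLS line through calibration points; interpolation only."""

    x: np.ndarray
    y: np.ndarray
    slope: float
    intercept: float
    x_semantics: str  # 'migration_distance' | 'fmol'

    @classmethod
    def fit(cls, x, y, x_semantics: str) -> "StandardCurve":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 2:
            raise FitError("a standard curve needs at least 2 points")
        res = sps.linregress(x, y)
        return cls(x, y, float(res.slope), float(res.intercept), x_semantics)

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


def ladder_curve(sizes_nt, migration_distances) -> StandardCurve:
    """Standard curve of log10(size) versus distance migrated."""
    return StandardCurve.fit(migration_distances, np.log10(sizes_nt),
                             "migration_distance")


def estimate_size(ladder: StandardCurve, migration_distance: float) -> float:
    """Band size in nt from migration distance, via the log-linear ladder."""
    lo, hi = ladder.x.min(), ladder.x.max()
    if not (lo <= migration_distance <= hi):
        raise RangeError(
            f"distance {migration_distance} outside ladder range [{lo}, {hi}]")
    return float(10.0 ** ladder.predict(migration_distance))


def standards_curve(fmol, intensities) -> StandardCurve:
    """Intensity versus known fmol of in vitro transcribed standards."""
    return StandardCurve.fit(fmol, intensities, "fmol")


def quantify_by_standards(standards: StandardCurve,
                          sample_intensity: float) -> float:
    """Absolute amount (fmol) of a sample band by inverse regression."""
    lo, hi = standards.y.min(), standards.y.max()
    if not (lo <= sample_intensity <= hi):
        raise RangeError(
            f"intensity {sample_intensity} outside standards range [{lo}, {hi}]")
    if standards.slope == 0:
        raise FitError("flat standard curve cannot be inverted")
    return float((sample_intensity - standards.intercept) / standards.slope)


def read_decay_table(path) -> list[DecaySeries]:
    """TSV/CSV with columns time_min, band, control[, replicate]."""
    import pandas as pd
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "replicate" in df.columns:
        return [
            normalize_decay(g["time_min"], g["band"], g["control"])
            for _, g in df.groupby("replicate")
        ]
    return [normalize_decay(df["time_min"], df["band"], df["control"])]
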