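"""Rifampicin-chase half-lives, gel sizing and absolute quantification.

Normalises band intensities to a 16S-style loading control, fits mono- and
biphasic log10-linear decays (t1/2 = -log10(2)/slope, initial slope for
biphasic curves), sizes a band from a DNA-ladder standard curve and
converts a band intensity to fmol with in vitro transcribed standards.
"""

import numpy as np

from ligrseq import (estimate_size, fit_halflife, ladder_curve,
                     normalize_decay, quantify_by_standards, standards_curve)

# -- monophasic decay: band fades with t1/2 = 6 min, control steady -------
times = np.array([0.0, 2.0, 4.0, 8.0, 15.0, 22.0, 30.0])
band = 5000.0 * 2.0 ** (-times / 6.0)
control = np.full(times.size, 800.0)
series = normalize_decay(times, band, control)
fit = fit_halflife(series)
print(f"monophasic fit: slope={fit.slope:.5f} log10(%)/min, "
      f"t1/2={fit.label}, model={fit.model}")

# -- biphasic decay: fast phase (t1/2=5 min) then slow (10 min) -----------
t = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0])
fast, slow = -np.log10(2) / 5.0, -np.log10(2) / 10.0
logpct = np.where(t <= 10, 2 + fast * t, 2 + fast * 10 + slow * (t - 10))
bi = fit_halflife(normalize_decay(t, 10.0 ** logpct, np.ones(t.size)))
print(f"biphasic fit: model={bi.model}, breakpoint={bi.breakpoint:g} min, "
      f"initial-slope t1/2={bi.label}")

# -- a non-decaying RNA is censored at the end of the time course ---------
stable = fit_halflife(normalize_decay(times, control, control), t_max=30)
print(f"stable RNA: t1/2 {stable.label} (censored={stable.censored})")

# -- gel sizing from a ladder: log10(size) vs distance migrated -----------
ladder = ladder_curve([622, 527, 404, 307, 242, 160],
                      [1.0, 1.35, 1.9, 2.5, 3.05, 3.95])
d = 2.2
print(f"band at {d} cm migrates like {estimate_size(ladder, d):.0f} nt")

# -- absolute sRNA amount from fmol standards -----------------------------
curve = standards_curve([2.0, 5.0, 10.0, 20.0], [410.0, 1020.0, 2050.0, 4100.0])
sample = 2110.0
print(f"sample band of intensity {sample:g} contains "
      f"{quantify_by_standards(curve, sample):.1f} fmol")
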