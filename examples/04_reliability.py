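"""Intraclass correlation of a subjects-by-sessions measure table.

Builds two tables with known variance structure — one with stable
per-subject values across sessions, one with resampled values — computes the
ICC with its 95% CI and category band, and tests their equality with the
F-based comparison.
"""

import numpy as np

from leidakit import compare_icc, icc

rng = np.random.default_rng(0)
n, s = 24, 3
subject_effect = rng.normal(size=(n, 1))

stable = subject_effect + 0.5 * rng.normal(size=(n, s))  # strong subject signature
noisy = subject_effect + 2.0 * rng.normal(size=(n, s))  # session noise dominates

for name, x in [("stable", stable), ("noisy", noisy)]:
    res = icc(x)
    print(f"{name:>6s}: ICC = {res.icc_scaled:5.1f} "
          f"(95% CI {res.ci_low:.0f} to {res.ci_high:.0f}) -> {res.category}")

comp = compare_icc(stable, noisy)
print(f"equality F({comp.df1}, {comp.df2}) = {comp.f_stat:.2f}, p = {comp.p:.2g}")
# the scaled ICC runs from -100 to 100; bands: poor <= 20 < fair <= 40 <
# moderate <= 60 < substantial <= 80 < almost perfect
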