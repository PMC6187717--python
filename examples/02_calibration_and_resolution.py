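"""Calibration and resolution: fit the viscosity-vs-passage-time line from
synthetic water–glycerol standards and estimate the instrument resolution
from two adjacent viscosity populations.
"""

import numpy as np

import dropvisc as dv
from dropvisc.calibration import fit_gaussian, resolution
from dropvisc.synthetic import generate_calibration_set

instrument = dv.default_instrument()
rng = np.random.default_rng(1)

# five standards, ten transits each, with the default timing-noise model
standards = generate_calibration_set([1, 5, 10, 20, 30], instrument, n_rep=10, rng=rng)
cal = dv.fit_viscosity_calibration(standards["measured_value"], standards["known_value"])
print(f"fitted line: μ = {cal.slope:.4f}·Δt {cal.intercept:+.2f}  (R² = {cal.r_squared:.6f})")
mu, se = dv.viscosity_from_time(109.5, cal)
print(f"inversion:  Δt = 109.5 s  ->  μ = {mu:.2f} ± {se:.3f} cP")

# resolution: 1000 transits each at 1.0 and 1.1 cP
s1 = generate_calibration_set([1.0], instrument, n_rep=1000, rng=rng)
s2 = generate_calibration_set([1.1], instrument, n_rep=1000, rng=rng)
m1, sd1 = fit_gaussian(s1["measured_value"])
m2, sd2 = fit_gaussian(s2["measured_value"])
pooled = np.sqrt((sd1**2 + sd2**2) / 2)
est = resolution(pooled, cal)
print(f"passage-time Gaussians: {m1:.3f} ± {sd1:.4f} s  vs  {m2:.3f} ± {sd2:.4f} s")
print(f"two-sigma resolution: {est.resolution:.4f} cP")

# The fit recovers the affine transit law with R² ≈ 0.99999 and the two
# populations, 0.1 cP apart, sit ~4 timing SDs apart: the smallest viscosity
# step resolvable from a single transit is ~0.05 cP.
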