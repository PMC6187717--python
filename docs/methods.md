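# Methods

## Instrument model

The viscometer is modeled as two lumped hydrodynamic resistances in series
under a constant driving pressure Δp: the oil-filled channel (`Rc`,
Pa·s·m⁻³) and the sample plug (`Rd = k_d·μ_d`, with `k_d` in m⁻³ and `μ_d`
the plug viscosity in Pa·s). The volumetric flow rate is
`Q = Δp/(Rc + Rd) = S·v`, so the passage time over the sensor separation `l`
is `Δt = l·S·(Rc + k_d·μ_d)/Δp` — affine in viscosity, inversely
proportional to pressure. Assumptions: quasi-steady laminar flow, a single
plug in the loop, constant plug volume, temperature held at 37 °C (no
temperature dependence is modeled), and viscosity-independent `Rc`.

`Rc` and `k_d` are **not** computed ab initio. A bare Hagen–Poiseuille
estimate of the plug resistance ignores the lubricating oil film around the
plug and contradicts the measured sensitivity, so both constants are
back-solved from the measured two-point calibration at 100 mbar
(1 cP → 103 s, 30 cP → 116 s), giving `Δt = α + β·μ` with `β = 13/29 s/cP`
and `α = 103 − 13/29 s`, hence `Rc = α·Δp/(l·S) ≈ 2.04×10¹² Pa·s·m⁻³` and
`k_d = β·Δp/(l·S)` per Pa·s. A consequence worth noting: these constants give
a droplet-to-system resistance ratio of ≈1:135 for a 1.7 cP plug, not the
~1:500 quoted for the complete apparatus — the difference is attributable to
lead resistances outside the printed geometry. Nothing in the package
depends on that ratio.

The sensor separation `l` is not a printed constant; the default of 1.0 m is
chosen because the quoted capillary number (~2×10⁻⁴) together with
Δt ≈ 103 s implies `l = v·Δt ≈ 0.99 m`. It is a configuration parameter,
never hard-coded downstream.

Flow diagnostics: capillary number `Ca = μ_o·v/γ` with the oil viscosity
0.395 cP and interfacial tension 19 mN/m; interface shear rate estimated as
`c_s·v/r` with a calibrated lumped coefficient `c_s = 0.453` standing in for
the full film-flow solution (it reproduces ~11 s⁻¹ at the 100-mbar, 1 cP
operating point; at 24 cP it gives ≈10 s⁻¹ where ~9 s⁻¹ is quoted — a ~10%
mismatch inherent to the single-coefficient approximation, so the tests
treat the low-viscosity anchor as the only equality check).

Trace synthesis renders a windowed voltage trace per sensor (±1 s around the
plug's pass, 2 kHz): oil baseline 2.5 a.u., interior voltage
`V = 2.3102 − 0.20408·OD(s)` (the affine map through the measured anchor
pairs), a meniscus spike at each cap, and additive Gaussian noise of RMS
50 µV. Spikes are Gaussian bumps (amplitude 0.3 a.u., polarity configurable)
truncated at ±0.02 s with σ = 5 ms, so they cannot leak into the 10%-guarded
interior window at the reference operating point — this keeps the
"integrated signal equals the OD map exactly" identity exact in noise-free
runs. Timing jitter is a single draw per transit,
σ_Δt = 0.05·β/2 ≈ 11.2 ms, back-solved so the two-sigma resolution criterion
reproduces the instrument's 0.05 cP resolution; it is the dominant noise
term. Event-level simulation (emit Δt and integrated signal directly) is the
default for long campaigns; trace-level synthesis is capped at 200 transits
per call because a full 48-h campaign at trace level would be ~3×10⁷ samples
for no analytical benefit.

## Synthetic growth scenarios

The generator emulates a 48-h *E. coli* batch culture in a circulating
droplet, sampled every 10 min, 10 replicates. OD follows a logistic with
death-phase decline:

    OD(t) = OD0 + (ODmax − OD0)/(1 + e^(−k(t − t_i))) − m·max(0, t − t_s)

with OD0 = 0.05 a.u., ODmax = 2.83 a.u., t_i = 6 h. The logistic rate
k = 1 h⁻¹, stationary onset t_s = 12 h and death slope m = 0.0064 a.u./h are
not measured quantities; they are the minimal choices that reproduce the
qualitative phase picture and the observed 48-h OD spread (≈2.5–2.7 a.u.).

Viscosity is slaved to the OD rise up to the OD inflexion and relaxes
exponentially afterwards:

    t ≤ t_i:  μ = μ_base + (μ_max − μ_base)·ρ(t)^p,   ρ = (OD − OD0)/(OD(t_i) − OD0)
    t > t_i:  μ = μ_inf + (μ_max − μ_inf)·e^(−(t − t_i)/τ)

with μ_base = 1.83 cP, μ_inf = 5.5 cP, τ = 6 h, and a pressure-dependent
peak μ_max = 23.31 / 10.0 / 5.5 cP at 100 / 200 / 300 mbar (higher pressure
→ higher shear → weaker aggregation). The coupling exponent defaults to
p = 2 rather than a strictly linear coupling (p = 1): with the logistic tail
a linear coupling would already lift viscosity to ≈2.5 cP midway through the
lag phase, whereas the observed lag phase is rheologically quiet
(1.83 ± 0.38 cP). p = 2 keeps the lag-phase mean within ~0.05 cP of μ_base
while preserving continuity and the exact peak value μ(t_i) = μ_max. The
form remains C⁰ but not C¹ at the peak; the kink is intentional (the
post-peak relaxation is a different physical process, aggregate breakup).

Replicate variability enters as mean-one lognormal factors on μ_base, μ_max
and ODmax with CVs 0.21, 0.08 and 0.025, back-solved from the measured
replicate SDs (0.38/1.83, 1.86/23.31, 0.07/2.83). Spatial structure is
assigned by viscosity regime: uniform below 5 cP, 2–4 random Gaussian
patches between 5 and 15 cP pre-peak, a single conglomerate centered at
s = 0.88 (trailing quarter) above 15 cP pre-peak, uniform post-peak. Every
profile is normalized so its axial mean equals the plug OD exactly; the
5/15 cP thresholds are qualitative conventions. The CFU↔OD factor
(8×10⁸ CFU·mL⁻¹ per OD unit) is a conventional stand-in — no measured value
exists for this instrument — and is configurable.

What the generator does *not* emulate: mechanistic aggregation or motility,
oxygen transport, instrument drift, droplet-volume variation, or
non-Gaussian noise. Passing tests therefore demonstrate correctness of the
measurement chain under the stated noise model, not robustness to un-modeled
instrument pathologies.

## Signal processing and calibration

Spike detection uses `scipy.signal.find_peaks` with a prominence threshold
of 4× a robust noise estimate (median absolute successive difference scaled
to RMS), floored at 0.01 a.u. so pure-noise traces can never yield events.
With more than two qualifying spikes the outermost pair is taken (with a
warning). Timing uses the leading-edge convention (front spike to front
spike), which is insensitive to plug-length changes; the convention is
configurable in principle but no alternative is implemented. The interior
window shrinks the inter-spike interval by 10% per side to exclude meniscus
lensing; the integrated signal is the *time-averaged* interior voltage
(units a.u., directly comparable to the 1.8–2.3 a.u. calibration range),
not a raw time-integral, which would scale with plug speed.

Calibrations are ordinary least-squares lines with R², residual SD and
parameter-covariance-propagated standard errors; inversion outside the
fitted range warns rather than fails (growth runs legitimately reach
OD 2.83, above the 2.5 anchor). Factory lines: μ(Δt) from the two passage-time
anchors (slope scales ∝ Δp, intercept unchanged), OD(V) = −4.9·V + 11.32
from the voltage anchors. Resolution is quoted as 2·σ_Δt·(dμ/dΔt) — twice
the single-transit SD in viscosity units — a documented convention chosen
because it reproduces the quoted 0.05 cP from the calibration slope with a
single free parameter and matches the visual separation of passage-time
histograms 0.1 cP apart (exactly 4σ).

## Growth analysis

Series are smoothed with a centered moving average before differentiation or
peak-picking. The default window is 3 ticks (30 min): with the intentionally
kinked viscosity peak, a 5-tick window biases the detected peak ≈0.9 cP low
and displaces it by 2 ticks, breaking the expected coincidence of the
viscosity peak with the OD inflexion; 3 ticks keeps the bias ≈0.5 cP and the
coincidence within one tick while still averaging the (small) measurement
noise. Phase conventions, all configurable: lag ends at the last time the
smoothed OD is below OD0 + 5% of dynamic range; log ends when it first
exceeds the observed maximum − 5%; stationary ends at the first sustained
(3-tick) decline; curves with < 0.1 a.u. dynamic range count as flat
(sterile control → all-lag, no inflexion). The OD inflexion is the maximum
first difference of the smoothed curve, assigned to the right edge of the
steepest interval, earliest tie winning.

The negative-control invariance test fits an OLS slope of viscosity (and OD)
against time and passes when the 95% t-based CI covers zero. Under the
generator's Gaussian noise the CI has exactly 95% coverage, so over a finite
seed battery the pass rate fluctuates binomially around 95% — the acceptance
test's ≥95% pass-rate check over 200 fixed seeds holds (97% viscosity, 96%
OD) but is intrinsically near-critical, which is a property of the criterion,
not of the implementation.

## Numerical and reproducibility choices

Internally SI units (m, s, Pa, Pa·s); cP, mbar, mm, µL only at configuration
and I/O boundaries (1 cP = 1 mPa·s, 1 mbar = 100 Pa). Calibration constants
are stored as exact expressions (β = 13/29 s/cP, OD slope −0.5/2.45) so the
forward↔inverse loop is an identity to machine precision. A single seeded
`numpy.random.Generator` is threaded explicitly through every stochastic
operation; run manifests record seed, configuration snapshot and output
hashes, and identical seeds give bit-identical event records. Degenerate
inputs raise typed errors (no droplet, sensor order, degenerate fit, no
inflexion); out-of-validity operating points (μ > 50 cP; extrapolated
inversions) warn and proceed, since refusing would discard usable data.
Desk-scale guards refuse event campaigns above 10⁶ events and trace-level
campaigns above 200 transits.

Problem sizes used by the acceptance computations — 1000 transits per
population for the resolution estimate, 5 standards × 10 replicates for
calibration quality, 10 replicates × 289 ticks for growth recovery — match
the corresponding measurement campaigns of the instrument.

## Known limitations

- The affine Δt(μ) law is a lumped first approximation; film-flow physics
  enters only through the calibrated constants `k_d` and `c_s`.
- The shear-rate estimate carries ~10% error away from its calibration
  anchor; the pressure-dependence of the viscosity peak is imposed through
  the scenario table, not predicted from shear physics.
- Growth-curve functional forms are phenomenological; parameters beyond the
  anchored values (k, t_s, m, regime thresholds) are unconstrained
  conventions.
- Timing jitter is modeled pressure-independent; if jitter scaled with plug
  speed the resolution at 200/300 mbar would differ from the 100-mbar value
  by more than the model predicts.
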