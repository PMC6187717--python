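# dropvisc

Droplet-microfluidic viscometry, simulated end to end: a forward model of a
two-sensor plug-flow viscometer, the signal-processing and calibration chain
that turns sensor traces into viscosity and optical density, and growth-curve
analysis for bacterial cultures incubated inside a circulating microdroplet.

## The problem and the model

A 2.4 µL aqueous plug (growth medium, with or without an *E. coli* culture)
is driven through 0.8 mm ID FEP tubing by a constant pressure difference Δp,
carried by a fluorinated oil. By the Kirchhoff analogy the oil-filled channel
and the plug are hydrodynamic resistances in series:

```
Rc + Rd = Δp/Q = Δp/(S·v) ≅ Δp·Δt/(S·l),      Rd = k_d·μ_d
```

with `S = πd²/4` the tube cross-section, `l` the distance between the two
optical sensors, `v` the plug speed and `Δt` its sensor-to-sensor passage
time. Because `Rd ∝ μ_d` for a long plug (Hagen–Poiseuille), the passage time
is **affine in the plug viscosity** and inversely proportional to Δp:

```
Δt = l·S·(Rc + k_d·μ_d)/Δp
```

`Rc` and `k_d` are anchored to a measured two-point calibration
(1 cP → 103 s, 30 cP → 116 s at 100 mbar). The same sensors read the plug's
optical density: the time-averaged interior voltage maps linearly to OD
(1.8 a.u. ↔ OD 2.5, 2.3 a.u. ↔ OD 0.05), and sharp meniscus spikes delimit
the plug. A single transit therefore yields a simultaneous (viscosity, OD)
measurement; timing jitter of σ_Δt ≈ 11 ms gives a two-sigma viscosity
resolution of 0.05 cP.

A synthetic-data module stands in for the instrument: logistic OD growth with
a death-phase decline, viscosity slaved to the OD rise up to the OD inflexion
(peak 23.31 / 10 / 5.5 cP at 100 / 200 / 300 mbar) relaxing to ~5.5 cP,
axial aggregate structure (uniform → patchy → rear conglomerate → uniform),
replicate-level biological variability, and the sensor noise model.

## Worked example

```python
import numpy as np
import dropvisc as dv
from dropvisc.synthetic import GrowthScenario, generate_run

instrument = dv.default_instrument()
g, oil, net, _ = instrument
r = dv.passage_time(dv.DropletState.from_cp(30.0), g, net,
                    dv.OperatingPoint.from_mbar(100), oil=oil)
print(f"{r.passage_time:.1f} s")          # 116.0

events, truth = generate_run(GrowthScenario(), instrument, np.random.default_rng(0))
summaries = [dv.summarize(rec) for rec in dv.assemble(events)]
print(round(np.mean([s['visc_max_cP'] for s in summaries]), 2))   # 23.03
print(round(np.mean([s['od_max_au'] for s in summaries]), 2))     # 2.83
```

A 30 cP plug takes 116 s between the sensors (vs 103 s at 1 cP); running the
default 10-replicate 48-h scenario through the pipeline recovers a
replicate-mean viscosity peak of ≈23 cP at the OD inflexion (~6 h) and a
maximum OD of ≈2.83 a.u. The scripts in `examples/` walk through each
capability (forward model, calibration + resolution, growth runs, scan
profiles, negative control) and print annotated output; `dropvisc --help`
exposes the same pipeline as shell subcommands
(`simulate-calibration`, `calibrate`, `simulate-growth`, `detect`, `measure`,
`analyze`, `report`).

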