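"""Full pipeline on a synthetic 48-h bacterial growth campaign at 100 mbar:
simulate 10 replicates, invert events to (t, viscosity, OD), segment growth
phases and print the replicate-mean summary.
"""

import numpy as np

import dropvisc as dv
from dropvisc.growth import aggregate_replicates
from dropvisc.synthetic import GrowthScenario, generate_run

instrument = dv.default_instrument()
rng = np.random.default_rng(0)

scenario = GrowthScenario()  # 100 mbar, 10 replicates, 48 h at 10-min cadence
events, truth = generate_run(scenario, instrument, rng)
records = dv.assemble(events)
summaries = [dv.summarize(rec) for rec in records]

mean = {k: float(np.mean([s[k] for s in summaries])) for k in summaries[0]
        if isinstance(summaries[0][k], (int, float))}
print(f"replicates: {len(records)},  events: {len(events)}")
print(f"lag-phase viscosity : {mean['visc_baseline_cP']:6.2f} cP")
print(f"peak viscosity      : {mean['visc_max_cP']:6.2f} cP at t = {mean['t_visc_max_h']:.1f} h")
print(f"max OD              : {mean['od_max_au']:6.2f} a.u.")
print(f"48-h viscosity      : {mean['visc_final_cP']:6.2f} cP")
print(f"phases: lag ends {mean['lag_end_h']:.1f} h, OD inflexion {mean['od_inflexion_h']:.1f} h, "
      f"log ends {mean['log_end_h']:.1f} h")

agg = aggregate_replicates(records)
i = int(np.argmax(agg["visc_mean_cP"]))
print(f"aggregate peak: {agg['visc_mean_cP'][i]:.2f} ± {agg['visc_sd_cP'][i]:.2f} cP across replicates")

# Viscosity rises from ~1.8 cP through the log phase to a peak of ~23 cP at
# the OD inflexion (~6 h), then relaxes to ~5.5 cP by 48 h while OD tops out
# near 2.8 a.u. — the coupled growth/rheology signature this instrument reads.
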