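"""Metabolic inhibitors reveal what powers accumulation.

Generates paired control/treated accumulation experiments for a
protonophore (CCCP, collapses the proton motive force) and an ATP-synthase
blocker (DCCD), then estimates the effective inhibition delay of each from
the treated plateau and the control accumulation rate.
"""

import periphos as pp

params = pp.fig3_default_parameters()
events = [
    pp.InhibitorEvent(0.0, pp.InhibitorKind.CCCP),
    pp.InhibitorEvent(0.0, pp.InhibitorKind.DCCD),
]
tables = pp.generate_inhibitor_experiment(params, events)

ctrl = tables["control"].mean_over_replicates("P33", "ASW")
rate_t = ctrl["time_min"].to_numpy()
rate_v = ctrl["value_pct_of_added"].to_numpy()

for kind in ("CCCP", "DCCD"):
    treated = tables[kind].mean_over_replicates("P33", "ASW")
    plateau = treated["value_pct_of_added"].to_numpy()[-1]
    delay = pp.estimate_inhibition_delay(rate_t, rate_v, plateau)
    print(f"{kind}: accumulation plateaus at {plateau:.2f}% of added; "
          f"effective delay = {delay:.2f} min")

print()
print("Meaning: CCCP stops accumulation within ~4 min (as fast as it can "
      "reach the membranes), implicating the proton motive force directly; "
      "DCCD acts 3x more slowly, consistent with an indirect effect through "
      "ATP-pool rundown rather than a primary ATP-driven pump.")
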