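"""The dual-isotope pulse-chase experiment in silico.

Simulates the reference condition — a 1e-8 mol/l radiolabelled pulse at
t = 0 followed by a 100x cold-equivalent chase at t = 120 min — and shows
the two signatures of a periplasmic buffer: the chase floods the medium but
not the cell, and the pulse keeps being assimilated at an unchanged rate.
"""

import dataclasses

import numpy as np

import periphos as pp

params = pp.fig3_default_parameters()
design = pp.fig3_default_design()
traj = pp.simulate(params, design)

at = np.flatnonzero(traj.times == 120.0)[0]
residual = traj.seawater_conc("P33")[at]
chase = traj.seawater_conc("P32")[at]
print(f"residual pulse in seawater at 120 min: {residual:.3g} mol/l")
print(f"chase concentration at addition:       {chase:.3g} mol/l "
      f"({chase / residual:.0f}x the residual pulse)")

m = traj.pool("P33", "macromolecule")
pre = m[traj.times == 120.0][0] / 120.0
post = (m[traj.times == 300.0][0] - m[traj.times == 120.0][0]) / 180.0
print(f"pulse assimilation rate before chase: {pre:.3g} molecules/cell/min")
print(f"pulse assimilation rate after chase:  {post:.3g} molecules/cell/min "
      f"(ratio {post / pre:.3f})")

state = traj.state_at(180.0)
asw = pp.apply_measurement(state, "ASW", params)["P33"]
pfa = pp.apply_measurement(state, "PFA", params)["P33"]
print(f"washable/fixable pulse label at 180 min: (ASW - PFA)/PFA = "
      f"{(asw - pfa) / pfa:.1f}")

direct = dataclasses.replace(params, topology="direct")
traj_d = pp.simulate(direct, design)
md = traj_d.pool("P33", "macromolecule")
pre_d = md[traj_d.times == 120.0][0] / 120.0
post_d = (md[traj_d.times == 300.0][0] - md[traj_d.times == 120.0][0]) / 180.0
print(f"conventional buffer-free model: post-chase rate collapses "
      f"{pre_d / post_d:.1f}x")

print()
print("Meaning: with a periplasmic buffer the chase cannot dilute the "
      "already-accumulated pulse, so its assimilation continues unchanged; "
      "a conventional direct-uptake cell would show a >10x collapse. Most "
      "of the cell-associated pulse label stays in the washable (periplasmic "
      "+ labile) fraction rather than in macromolecules.")
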