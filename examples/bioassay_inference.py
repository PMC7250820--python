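"""Isotope-dilution bioassay: ambient P_i and uptake velocity from turnover.

Generates a concentration-series tracer-uptake experiment (with and without
measurement noise) and fits the dilution line T = (C_ambient + C_added) / v.
"""

import numpy as np

import periphos as pp

AMBIENT = 5e-9      # mol/l
VELOCITY = 1e-10    # mol/l/min
CONCS = (1e-9, 2e-9, 5e-9, 1e-8, 2e-8)
TIMES = (10.0, 20.0, 40.0)

clean = pp.isotope_dilution_fit(pp.generate_bioassay(AMBIENT, VELOCITY, CONCS, TIMES))
print(f"noise-free fit: ambient = {clean.ambient_conc:.4g} mol/l, "
      f"velocity = {clean.uptake_velocity:.4g} mol/l/min (truth: {AMBIENT:g}, {VELOCITY:g})")

noise = pp.NoiseModel(kind="lognormal", sigma=0.05, seed=11)
noisy = pp.isotope_dilution_fit(
    pp.generate_bioassay(AMBIENT, VELOCITY, CONCS, TIMES, noise)
)
print(f"one 5%-noise draw: ambient = {noisy.ambient_conc:.3g} "
      f"+/- {noisy.ambient_se:.2g} mol/l, velocity = {noisy.uptake_velocity:.3g} "
      f"+/- {noisy.velocity_se:.2g} mol/l/min")

errs = []
for draw in range(100):
    nm = pp.NoiseModel(kind="lognormal", sigma=0.05, seed=3000 + draw)
    fit = pp.isotope_dilution_fit(pp.generate_bioassay(AMBIENT, VELOCITY, CONCS, TIMES, nm))
    errs.append(abs(fit.ambient_conc / AMBIENT - 1))
print(f"median |relative error| of ambient over 100 draws: {np.median(errs):.1%}")

print()
print("Meaning: the turnover-time regression recovers nanomolar ambient "
      "phosphate and the community uptake velocity exactly from clean data, "
      "and to within ~10% under realistic 5% measurement noise.")
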