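"""Fitting the compartment model to noisy pulse-chase data.

Generates a Poisson-noise pulse-chase dataset from known parameters, fits
the model by seeded multi-start least squares, and bootstraps confidence
intervals for the clearance.
"""

import dataclasses

import periphos as pp

truth = dataclasses.replace(
    pp.fig3_default_parameters(), import_vmax=200.0, assim_rate=0.05
)
design = pp.ExperimentDesign(
    cell_density=2e10,
    additions=(
        pp.Addition(0.0, "P33", 1e-8),
        pp.Addition(120.0, "P32", 1e-6),
    ),
    sampling_times=(30.0, 60.0, 120.0, 180.0, 300.0),
    protocols=(pp.Protocol.ASW, pp.Protocol.PFA),
    replicates=2,
)

tc = pp.generate_pulse_chase(truth, design, pp.NoiseModel(kind="poisson", seed=21))
fit = pp.fit_kinetics(tc, design, truth, n_starts=4, seed=1)

print("parameter            truth        estimate     rel. error")
for name, est in fit.estimates.items():
    tv = getattr(truth, name)
    print(f"{name:<20} {tv:<12.4g} {est:<12.4g} {abs(est / tv - 1):.1%}")

ci = pp.bootstrap_ci(fit, tc, design, truth, n_boot=100, seed=2)
lo, hi = ci["clearance_cl"]
print(f"\n95% bootstrap CI for clearance: [{lo:.3g}, {hi:.3g}] l/cell/min "
      f"(truth {truth.clearance_cl:g})")

print()
print("Meaning: from a single noisy dual-isotope experiment the clearance, "
      "import capacity, assimilation rate and fixation-retention fraction "
      "are all recoverable, with calibrated uncertainty from a case-"
      "resampling bootstrap.")
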