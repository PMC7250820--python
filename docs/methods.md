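# Methods

## Model

`periphos.kinetics` integrates a dual-isotope compartment model of P_i
handling by a single marine bacterial cell population. Two radiotracer
channels (`P33` pulse, `P32` chase) move independently through five pools:

```
seawater --(clearance CL)--> periplasm --(PstSCAB import)--> cytoplasmic
labile pool --(k_assim)--> macromolecules        [+ optional surface adsorption]
```

Per channel `c`, with cell pools in molecules/cell and the seawater pool
kept as the per-cell equivalent `S_c = C_c N_A / rho` (so each channel's
total is conserved exactly between additions):

```
a_c     = g(t) · light(t) · CL · rho · S_c           (accumulation)
imp_c   = import_gate(t) · Vmax · P_c / (K + P_c)    (import)
dP_c/dt = a_c − imp_c − k_leak P_c
dL_c/dt = imp_c − k_assim L_c
dM_c/dt = k_assim L_c
dS_c/dt = −a_c − k_ads rho S_c + k_des A_c + k_leak P_c
dA_c/dt = k_ads rho S_c − k_des A_c
```

`K = Km · N_A · V_peri` converts the import half-saturation concentration
(referenced to the periplasm volume) into molecules. With `Km = 10⁻⁷ mol/l`
and `V_peri = 2·10⁻¹⁷ l`, `K ≈ 1.2` molecules — the importer is saturated
whenever the buffer holds more than a few molecules.

**Per-channel import.** Each channel saturates its import flux
independently (`imp_c` depends on `P_c` alone) rather than sharing one
Michaelis–Menten flux in proportion to periplasmic fractions. This is a
deliberate model choice: with `K` of order one molecule, a *shared* flux
would dilute the pulse channel's import ~100-fold as soon as the chase
floods the buffer, which contradicts the defining observation the model
exists to capture — macromolecular incorporation of the pulse continues at
an unchanged rate through a 100× chase. A buffered stock that keeps the
transporter saturated imports both tracers in parallel; the per-channel
form encodes exactly that. The acceptance test
`test_buffer_decouples_assimilation_from_the_medium` checks the resulting
<10% rate change directly.

**Direct (buffer-free) topology.** `topology="direct"` implements the
conventional alternative for contrast: no periplasmic pool; uptake is a
single competitively shared Michaelis–Menten flux on *seawater*
concentrations, `uptake_c = g·light·CL·rho·S_c · Km / (Km + C_tot)`,
routed straight to the labile pool. It matches the buffered model's
clearance in the linear regime (`C_tot ≪ Km`) and collapses the pulse
channel's assimilation 11.2-fold after the chase — the classical
pulse-chase dilution the buffered data rule out.

**Measurement operators** map a state to what each bench protocol detects
(molecules/cell): seawater wash `ASW` = adsorbed + periplasm + labile +
macromolecules; hypotonic wash `DW` = labile + macromolecules (the wash
bursts the outer membrane and releases adsorbed + periplasmic label);
`PFA` = macromolecules + `f_pfa` × periplasm (a small crosslinked,
PstS-bound fraction); `TCA` = macromolecules only; `effluent` = dissolved
label as its per-cell equivalent, so cell + effluent sums to the amount
added.

**Inhibitors** act as piecewise-constant gates: CCCP and DBMIB (PMF
collapse) zero the accumulation flux `cccp_delay` minutes after addition
(membrane-integration time); DCCD (ATP-synthase block) zeroes both
accumulation and import after `dccd_delay` = 3 × `cccp_delay`, consistent
with an indirect effect through ATP-pool rundown; ionophores multiply the
clearance by a given factor. A `light_factor` multiplies clearance while
the light schedule is on.

## Parameters (fig3-default calibration)

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `clearance_cl` | 1.8e-13 | l cell⁻¹ min⁻¹ | back-computed from a 3 h quota-doubling time at 10⁻⁶ mol/l for a 1.93·10⁷-atom P quota: `CL = quota / (c · N_A · 180 min)` |
| `import_vmax` | 20 | molecules cell⁻¹ min⁻¹ | of order the observed macromolecular incorporation rate; keeps the 3 h labile/assimilated ratio in the observed 10–20× band |
| `import_km` | 1e-7 | mol l⁻¹ | periplasm-referenced import half-saturation; any value ≪ buffered concentrations behaves identically (saturated) |
| `periplasm_volume` | 2e-17 | l | ~0.8 µm coccus with a ~10 nm shell (`periplasm_shell_volume`) |
| `assim_rate` | 0.5 | min⁻¹ | labile pool turns over in ~2 min; calibrated a priori from the observation that under CCCP, tracer reaches fixable macromolecules in under a minute — assimilation is fast compared with sampling |
| `pfa_retained_fraction` | 0.05 | — | small crosslinked periplasmic fraction retained by PFA |
| `cccp_delay` / `dccd_delay` | 4 / 12 | min | onset delays reproduced by the delay estimator on generated data |
| cell density (design) | 2e10 | cells l⁻¹ | 2·10⁷ cells ml⁻¹, inside the typical bloom-culture range; with `clearance_cl` it leaves a residual pulse of 6.5·10⁻⁹ mol/l at the 2 h chase (within the observed 4.5–7·10⁻⁹ window) |

The calibration was fixed from these printed quantities before the
acceptance values were computed; no parameter was adjusted against a test
outcome.

## Inference

`fit_kinetics` couples the simulator with the measurement operators:
residuals are formed on the percent-of-added scale after a square-root
transform (variance-stabilizing for Poisson counting noise), and rates are
optimized in log10 space within strictly positive bounds
(`scipy.optimize.least_squares`, trust-region reflective) from a seeded
multi-start (log-uniform draws plus the user's initial value). Standard
errors come from the Gauss–Newton covariance in log space; `bootstrap_ci`
refits case-resampled records (≥2 replicates required) from the point
estimate.

`import_km` is fixed by default: when the buffer keeps the importer
saturated, pulse-chase data carry no information separating `Km` from
`Vmax`.

**Identifiability of `assim_rate`.** Under the fig3-default calibration
the labile pool turns over in ~2 min while sampling is ≥15 min apart: any
sufficiently fast `assim_rate` predicts identical data to counting
precision, so the parameter is structurally unidentifiable *in that
regime* (this is a property of the design, not a solver failure). The
parameter-recovery study therefore generates data from a regime where
every fitted parameter is informative at the stated counting depth
(`import_vmax = 200`, `assim_rate = 0.05`, all else fig3-default); the
recovery tolerances (clearance within 20%, others within 30%, ≥8/10
seeds) are checked there.

## Synthetic-data generator: scope

`generate_pulse_chase` applies the design's protocols at each sampling
time and replicate, converts to percent of the tracer added to each
channel (cumulative additions up to the sampling time as denominator), and
adds noise: Poisson scintillation counting (default 10⁴ expected counts at
a 100% signal) or multiplicative lognormal error. Seeds are mandatory for
stochastic noise and runs are bit-identical given a seed. The generator
shares the simulator's physics exactly — it emulates measurement, not an
independent data-generating process — so generator/estimator round trips
test the estimators, not the model's correspondence to any real
experiment. `generate_bioassay` draws from the turnover model
`f = 1 − exp(−t·v/(C_amb + C_a))`; fractions pushed to ≥1 by noise are
clipped to 1 − 10⁻⁶, which slightly biases extreme-uptake points low.

## Numerical choices

- Piecewise LSODA integration with breakpoints at every addition,
  inhibitor onset and light switch; the solver restarts at each
  breakpoint, and outputs at an event time report the post-event state.
- `rtol = 10⁻¹⁰`, `atol = 10⁻³` molecules: tight enough that per-channel
  label totals are conserved to better than 10⁻⁹ relative between
  additions (asserted in the acceptance suite). States more negative than
  `max(10⁻⁶, 10·atol)` abort the run; smaller excursions are clamped to 0.
- In the linear-import regime the model is verified against the exact
  matrix-exponential solution to better than 10⁻⁶ relative (with solver
  tolerances tightened to `rtol = 10⁻¹²`, `atol = 10⁻⁹` so the comparison
  is not floor-limited by `atol`).
- Through-origin regressions are used where the model fixes the intercept
  exactly (depletion fits, turnover fits, control accumulation rate);
  ordinary least squares with free intercept elsewhere (isotope-dilution
  line, SXRF calibration), with delta-method standard errors.

## Reduced study sizes in the test suite

To stay within a small offline CPU budget, the test suite scales down two
Monte-Carlo studies rather than skipping them: the bootstrap coverage
check uses 5 independent datasets × 100 bootstrap refits on a coarse
design (nominal 95% interval must cover the generating clearance in ≥3/5),
and the noisy-bioassay study uses 100 draws. The recovery study (10 seeds,
full reference design) runs at full size.

## Limitations

- The model is a population-average, well-mixed description: no
  cell-to-cell heterogeneity, no depletion boundary layers, no growth or
  dilution of the cell population over the run.
- Periplasmic retention is first-order and PMF-independent by default
  (`periplasm_leak = 0`); the mechanism holding accumulated P_i against
  the gradient is not modelled, only its kinetic consequence.
- Inhibitor action is an idealized step gate after a fixed delay; real
  onset is graded.
- The direct-topology contrast is a modelling construct for hypothesis
  comparison, not a calibrated description of any organism.
- `paper_style` rounding (1–2 significant figures) is for reproducing
  headline figures; all internal computation is full precision.
- The generator's noise menu (Poisson counting, lognormal multiplicative)
  omits systematic errors such as filter losses, quench variation or
  cross-channel spillover in dual-label counting.
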