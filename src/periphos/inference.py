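"""Fit the pulse-chase compartment model to tracer time courses.

The objective couples :func:`periphos.kinetics.simulate` with the
wash/fixation measurement operators: for a candidate parameter vector the
model is integrated once over the design, predictions are read off at every
observed (time, channel, protocol) and compared with the data on the
percent-of-added scale after a square-root transform (variance-stabilizing
for Poisson-like counting noise; an unweighted option exists).

Rates are optimized in log10 space inside user-supplied bounds with a
seeded multi-start (log-uniform draws plus the user's init); ties are broken
by lowest objective, then lowest clearance.  ``import_km`` is fixed by
default: pulse-chase data at two concentrations cannot separate the import
half-saturation from Vmax when the buffer keeps the importer saturated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateDataError, NonConvergenceError
from .kinetics import (
    CHANNELS,
    ExperimentDesign,
    KineticParameters,
    Protocol,
    apply_measurement,
    simulate,
)
from .synthetic import TracerTimeCourse

__all__ = ["FitResult", "fit_kinetics", "bootstrap_ci", "DEFAULT_BOUNDS"]

#: Parameters fitted by default and their default (lo, hi) bounds.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "clearance_cl": (1e-15, 1e-11),
    "import_vmax": (1e-1, 1e4),
    "assim_rate": (1e-3, 1e1),
    "pfa_retained_fraction": (1e-3, 5e-1),
}


@dataclass(frozen=True)
class FitResult:
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    residual_sum_squares: float
    convergence_flag: bool
    n_observations: int
    seed: int
    bounds: dict[str, tuple[float, float]]

    def as_parameters(self, base: KineticParameters) -> KineticParameters:
        return replace(base, **self.estimates)


def _predict_pct(
    params: KineticParameters,
    design: ExperimentDesign,
    times: np.ndarray,
    channels: list[str],
    protocols: list[str],
    rtol: float,
) -> np.ndarray:
    traj = simulate(params, design, grid=np.unique(times), rtol=rtol)
    cache: dict[tuple[float, str], dict[str, float]] = {}
    pred = np.empty(times.size)
    for i, (t, ch, proto) in enumerate(zip(times, channels, protocols)):
        key = (t, proto)
        if key not in cache:
            cache[key] = apply_measurement(traj.state_at(t), proto, params)
        added = design.added_molecules_per_cell(ch, t)
        pred[i] = 0.0 if added == 0 else cache[key][ch] / added * 100.0
    return pred


def fit_kinetics(
    timecourses: TracerTimeCourse,
    design: ExperimentDesign,
    init: KineticParameters,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_starts: int = 8,
    sqrt_weighting: bool = True,
    solver_rtol: float = 1e-8,
) -> FitResult:
    """Weighted least-squares fit of the kinetic parameters.

    Parameters named in ``bounds`` (default: clearance, Vmax, assimilation
    rate and the PFA retention fraction) are fitted; everything else stays
    at its ``init`` value.  ``bounds`` must enclose ``init``.
    """
    bounds = dict(bounds) if bounds is not None else dict(DEFAULT_BOUNDS)
    names = list(bounds)
    for name in names:
        lo, hi = bounds[name]
        v = getattr(init, name)
        if not (lo <= v <= hi):
            raise ValueError(f"init.{name}={v} outside bounds ({lo}, {hi})")
        if lo <= 0:
            raise ValueError("bounds must be strictly positive (log-space search)")

    df = timecourses.frame
    bad = set(df["protocol"]) - {p.value for p in design.protocols}
    if bad:
        raise ValueError(f"data protocols {bad} not in the design")
    obs = df["value_pct_of_added"].to_numpy(dtype=float)
    if not np.any(obs > 0):
        raise DegenerateDataError("all observations are zero")
    times = df["time_min"].to_numpy(dtype=float)
    channels = list(df["channel"])
    protocols = list(df["protocol"])

    lo = np.log10([bounds[n][0] for n in names])
    hi = np.log10([bounds[n][1] for n in names])

    def residuals(theta: np.ndarray) -> np.ndarray:
        params = replace(init, **{n: 10.0 ** th for n, th in zip(names, theta)})
        pred = _predict_pct(params, design, times, channels, protocols, solver_rtol)
        if sqrt_weighting:
            return np.sqrt(pred) - np.sqrt(obs)
        return pred - obs

    rng = np.random.default_rng(seed)
    starts = [np.log10([getattr(init, n) for n in names])]
    starts += [rng.uniform(lo, hi) for _ in range(max(0, n_starts - 1))]

    best = None
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10, gtol=1e-10)
        except Exception:
            continue
        if not sol.success:
            continue
        key = (sol.cost, 10.0 ** sol.x[names.index("clearance_cl")] if "clearance_cl" in names else 0.0)
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise NonConvergenceError("no optimizer start converged")
    sol = best[1]

    estimates = {n: float(10.0 ** th) for n, th in zip(names, sol.x)}
    # covariance in log10 space via the Gauss-Newton approximation
    n_obs = obs.size
    dof = max(n_obs - len(names), 1)
    sigma2 = 2.0 * sol.cost / dof
    try:
        jtj = sol.jac.T @ sol.jac
        cov = sigma2 * np.linalg.inv(jtj)
        se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_log = np.full(len(names), np.nan)
    ses = {
        n: float(math.log(10.0) * estimates[n] * s)
        for n, s in zip(names, se_log)
    }
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        residual_sum_squares=float(2.0 * sol.cost),
        convergence_flag=True,
        n_observations=int(n_obs),
        seed=seed,
        bounds=bounds,
    )


def bootstrap_ci(
    fit: FitResult,
    timecourses: TracerTimeCourse,
    design: ExperimentDesign,
    init: KineticParameters,
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Case-resampling bootstrap percentile intervals for the fitted parameters.

    Records (replicate x time x protocol x channel rows) are resampled with
    replacement; each resample is refitted from the point estimate (single
    start — the standard bootstrap-refit shortcut).  Requires >= 2
    replicates so resampling carries real measurement variability.
    """
    if not fit.convergence_flag:
        raise ValueError("bootstrap requires a converged fit")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    df = timecourses.frame
    if df["replicate"].nunique() < 2:
        raise ValueError("bootstrap needs >= 2 replicates")

    point = fit.as_parameters(init)
    rng = np.random.default_rng(seed)
    names = list(fit.bounds)
    draws = {n: [] for n in names}
    n = len(df)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = TracerTimeCourse(
            df.iloc[idx]
            .reset_index(drop=True)
            .assign(replicate=np.arange(n))  # re-key to keep records unique
        )
        bfit = fit_kinetics(
            resampled, design, point, bounds=fit.bounds,
            seed=int(rng.integers(0, 2**31 - 1)), n_starts=1,
        )
        for nm in names:
            draws[nm].append(bfit.estimates[nm])
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {
        nm: (float(np.percentile(draws[nm], lo_q)), float(np.percentile(draws[nm], hi_q)))
        for nm in names
    }
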