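"""Inference procedures around the tracer experiments.

* isotope-dilution concentration-series bioassay (ambient P_i concentration
  and community uptake velocity from turnover times),
* clearance estimation from tracer-depletion time courses,
* micro-SXRF (synchrotron X-ray fluorescence) cellular P quota calibration,
* genome-equivalent arithmetic,
* inhibition-delay estimation from paired control/treated time courses.

The bioassay rests on the turnover linearization: if a community removes
tracer exponentially with turnover time ``T``, the fraction taken up by
time ``t`` is ``f = 1 - exp(-t/T)``, and under substrate saturation
``T = (C_amb + C_a) / v`` is linear in the added concentration ``C_a`` —
so the regression of fitted turnover times on added concentration yields
the ambient concentration (x-intercept magnitude = intercept/slope) and the
uptake velocity (1/slope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .constants import AVOGADRO, PHOSPHORUS_MOLAR_MASS
from .exceptions import DegenerateDataError, DegenerateDesignError

__all__ = [
    "BioassayEntry",
    "BioassaySeries",
    "IsotopeDilutionFit",
    "turnover_time",
    "isotope_dilution_fit",
    "ClearanceFit",
    "clearance_from_depletion",
    "SxrfCalibration",
    "SxrfResult",
    "sxrf_quantify",
    "genome_p_equivalents",
    "estimate_inhibition_delay",
]


# --------------------------------------------------------------------------
# isotope-dilution bioassay
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BioassayEntry:
    """One incubation: added concentration, time, and fraction taken up."""

    added_conc: float       # mol l^-1
    time_min: float
    fraction_taken_up: float

    def __post_init__(self) -> None:
        if self.added_conc < 0:
            raise ValueError("added_conc must be >= 0")
        if self.time_min <= 0:
            raise ValueError("time_min must be > 0")
        if not 0 <= self.fraction_taken_up < 1:
            raise ValueError("fraction_taken_up must be in [0, 1)")


@dataclass(frozen=True)
class BioassaySeries:
    """Concentration-series tracer-uptake data for isotope dilution."""

    entries: tuple[BioassayEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if not self.entries:
            raise ValueError("a bioassay series needs at least one entry")

    @property
    def added_concs(self) -> np.ndarray:
        return np.unique([e.added_conc for e in self.entries])


@dataclass(frozen=True)
class IsotopeDilutionFit:
    ambient_conc: float          # mol l^-1
    uptake_velocity: float       # mol l^-1 min^-1
    ambient_se: float
    velocity_se: float
    turnover_times: dict[float, float]  # added_conc -> T-hat (min)
    slope: float
    intercept: float


def turnover_time(fraction: float, t: float) -> float:
    """Turnover time ``T = -t / ln(1 - f)`` from a single uptake fraction."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be strictly between 0 and 1")
    if t <= 0:
        raise ValueError("t must be > 0")
    return -t / math.log1p(-fraction)


def _turnover_from_points(times: np.ndarray, fractions: np.ndarray) -> float:
    """Through-origin log-linear regression of remaining fraction vs time.

    ``ln(1 - f) = -t / T``; the through-origin form encodes the model's
    ``f(0) = 0`` exactly.
    """
    remaining = 1.0 - fractions
    if np.any(remaining <= 0):
        raise ValueError("fractions must be < 1 for the log-linear fit")
    lr = np.log(remaining)
    slope = float(np.dot(times, lr) / np.dot(times, times))
    if slope >= 0:
        raise DegenerateDesignError("no net uptake: nonnegative depletion slope")
    return -1.0 / slope


def isotope_dilution_fit(series: BioassaySeries) -> IsotopeDilutionFit:
    """Estimate ambient P_i concentration and uptake velocity.

    Per added concentration, the turnover time is fitted from all its time
    points by log-linear regression; the fitted turnover times are then
    regressed (ordinary least squares) on the added concentration under
    ``T = (C_amb + C_a) / v``.
    """
    by_conc: dict[float, list[BioassayEntry]] = {}
    for e in series.entries:
        by_conc.setdefault(e.added_conc, []).append(e)
    if len(by_conc) < 2:
        raise ValueError("isotope dilution needs >= 2 distinct added concentrations")

    t_hat: dict[float, float] = {}
    for ca, entries in by_conc.items():
        times = np.array([e.time_min for e in entries], dtype=float)
        fracs = np.array([e.fraction_taken_up for e in entries], dtype=float)
        t_hat[ca] = _turnover_from_points(times, fracs)

    ca_arr = np.array(sorted(t_hat), dtype=float)
    t_arr = np.array([t_hat[c] for c in ca_arr], dtype=float)
    x = sm.add_constant(ca_arr)
    fit = sm.OLS(t_arr, x).fit()
    intercept, slope = fit.params
    if slope <= 0:
        raise DegenerateDesignError("turnover times do not increase with added P_i")
    se_int, se_slope = fit.bse if len(ca_arr) > 2 else (float("nan"), float("nan"))
    c_amb = intercept / slope
    v = 1.0 / slope
    # delta-method standard errors
    if np.isfinite(se_slope):
        cov = fit.cov_params()
        g = np.array([1.0 / slope, -intercept / slope**2])
        c_amb_se = float(np.sqrt(g @ cov @ g))
        v_se = float(se_slope / slope**2)
    else:
        c_amb_se = v_se = float("nan")
    return IsotopeDilutionFit(
        ambient_conc=float(c_amb),
        uptake_velocity=float(v),
        ambient_se=c_amb_se,
        velocity_se=v_se,
        turnover_times=t_hat,
        slope=float(slope),
        intercept=float(intercept),
    )


# --------------------------------------------------------------------------
# clearance from tracer depletion
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClearanceFit:
    clearance_cl: float       # l cell^-1 min^-1
    depletion_rate: float     # min^-1 (= CL * rho)
    n_used: int
    nonmonotone_warning: bool


def clearance_from_depletion(
    times: np.ndarray,
    remaining_fractions: np.ndarray,
    cell_density: float,
    initial_conc: float | None = None,
    detection_floor_conc: float = 1e-15,
) -> ClearanceFit:
    """Clearance rate from a tracer-depletion time course.

    Fits ``ln F = -CL rho t`` through the origin (``F(0) = 1`` by
    construction).  If ``initial_conc`` is given, points whose implied
    concentration falls below ``detection_floor_conc`` (the scintillation
    detection limit, ~1e-15 mol l^-1) are censored from the fit.
    """
    if cell_density <= 0:
        raise ValueError("cell_density must be > 0")
    times = np.asarray(times, dtype=float)
    fr = np.asarray(remaining_fractions, dtype=float)
    if times.shape != fr.shape or times.size < 2:
        raise ValueError("need >= 2 (time, fraction) points of equal length")
    if np.any(fr <= 0) or np.any(fr > 1):
        raise ValueError("remaining fractions must be in (0, 1]")

    keep = np.ones_like(fr, dtype=bool)
    if initial_conc is not None:
        keep &= fr * initial_conc >= detection_floor_conc
    times_k, fr_k = times[keep], fr[keep]
    if times_k.size < 2 or np.all(fr_k == fr_k[0]):
        raise DegenerateDataError("not enough informative depletion points")

    # gross non-monotonicity: any increase larger than 3 sigma of the
    # residual scatter around the fitted exponential
    lf = np.log(fr_k)
    slope = float(np.dot(times_k, lf) / np.dot(times_k, times_k))
    resid = lf - slope * times_k
    sigma = float(np.std(resid)) if resid.size > 2 else 0.0
    order = np.argsort(times_k)
    increases = np.diff(lf[order])
    warn = bool(np.any(increases > max(3 * sigma, 1e-12)))

    if slope >= 0:
        raise DegenerateDataError("tracer fraction does not decrease with time")
    rate = -slope
    return ClearanceFit(
        clearance_cl=rate / cell_density,
        depletion_rate=rate,
        n_used=int(times_k.size),
        nonmonotone_warning=warn,
    )


# --------------------------------------------------------------------------
# micro-SXRF quota calibration
# --------------------------------------------------------------------------

#: Cell-number window in which the SXRF response is linear and detectable.
SXRF_LINEAR_RANGE: tuple[float, float] = (2e4, 7.5e5)


@dataclass(frozen=True)
class SxrfCalibration:
    """Linear calibration of P mass signal against sorted cell number."""

    points: tuple[tuple[float, float], ...]  # (cells_sorted, p_signal_g)
    slope: float        # g per cell
    intercept: float    # g (blank filter background)
    slope_through_origin: float
    linear_range: tuple[float, float] = SXRF_LINEAR_RANGE

    @classmethod
    def fit(cls, points) -> "SxrfCalibration":
        points = tuple((float(c), float(s)) for c, s in points)
        if len(points) < 2:
            raise ValueError("need >= 2 calibration points")
        cells = np.array([p[0] for p in points])
        sig = np.array([p[1] for p in points])
        x = sm.add_constant(cells)
        res = sm.OLS(sig, x).fit()
        intercept, slope = res.params
        if slope <= 0:
            raise DegenerateDataError("calibration slope must be > 0 after fit")
        slope0 = float(np.dot(cells, sig) / np.dot(cells, cells))
        return cls(points=points, slope=float(slope), intercept=float(intercept),
                   slope_through_origin=slope0)

    def calibrant_atoms_per_cell(self) -> float:
        """P quota of the calibrant implied by the fitted slope."""
        return self.slope / PHOSPHORUS_MOLAR_MASS * AVOGADRO


@dataclass(frozen=True)
class SxrfResult:
    atoms_per_cell: float
    out_of_range: bool
    below_detection: bool


def sxrf_quantify(cal: SxrfCalibration, p_signal: float, cells: float) -> SxrfResult:
    """P atoms per cell from a measured P mass signal.

    The blank (calibration intercept) is subtracted; mass converts to atoms
    via the phosphorus molar mass and Avogadro's number.  A non-positive net
    signal yields a below-detection result rather than an exception, and
    samples outside the validated cell-number window are flagged.
    """
    if cells <= 0:
        raise ValueError("cells must be > 0")
    net = p_signal - cal.intercept
    lo, hi = cal.linear_range
    out = not (lo <= cells <= hi)
    if net <= 0:
        return SxrfResult(atoms_per_cell=0.0, out_of_range=out, below_detection=True)
    atoms = net / PHOSPHORUS_MOLAR_MASS * AVOGADRO / cells
    return SxrfResult(atoms_per_cell=atoms, out_of_range=out, below_detection=False)


def genome_p_equivalents(p_atoms: float, genome_bp: float, p_per_bp: float = 2) -> float:
    """Cellular P content expressed in genome equivalents.

    The default convention counts 2 phosphorus atoms per base pair (one per
    strand nucleotide); it is a parameter because reported genome-equivalent
    figures in the literature are not all consistent with a single value.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be > 0")
    if p_atoms < 0 or p_per_bp <= 0:
        raise ValueError("p_atoms must be >= 0 and p_per_bp > 0")
    return p_atoms / (p_per_bp * genome_bp)


# --------------------------------------------------------------------------
# inhibition delay
# --------------------------------------------------------------------------

def estimate_inhibition_delay(
    control_times: np.ndarray,
    control_values: np.ndarray,
    treated_plateau: float,
) -> float:
    """Effective inhibition delay (min): treated plateau / control rate.

    The control accumulation rate is the through-origin slope of the
    uninhibited time course (accumulation starts at zero); the treated
    culture accumulates at that same rate until the inhibitor takes effect,
    so its plateau divided by the control rate is the effective delay.
    """
    t = np.asarray(control_times, dtype=float)
    v = np.asarray(control_values, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 control points")
    rate = float(np.dot(t, v) / np.dot(t, t))
    if rate <= 0:
        raise DegenerateDataError("control shows no accumulation")
    return treated_plateau / rate
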