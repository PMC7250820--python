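"""Synthetic experiment generator.

Produces every input the analysis pipeline consumes — pulse-chase tracer
time courses, isotope-dilution bioassay series and inhibitor experiments —
with the statistical structure the estimators assume: per-protocol,
per-replicate records in percent of added tracer, Poisson scintillation
counting noise (or multiplicative lognormal pipetting error), explicit
seeds, and the same physics as :mod:`periphos.kinetics`.

The default pulse-chase condition is the ``fig3-default`` preset
(:mod:`periphos.presets`): 1e-8 mol l^-1 pulse at 0 min, 1e-6 mol l^-1
chase at 120 min, sampling out to 23 h, technical duplicates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import BioassayEntry, BioassaySeries
from .kinetics import (
    CHANNELS,
    Addition,
    CompartmentState,
    ExperimentDesign,
    InhibitorEvent,
    InhibitorKind,
    KineticParameters,
    Protocol,
    Trajectory,
    apply_measurement,
    simulate,
)

__all__ = [
    "TIMECOURSE_COLUMNS",
    "TracerTimeCourse",
    "NoiseKind",
    "NoiseModel",
    "generate_pulse_chase",
    "generate_bioassay",
    "generate_inhibitor_experiment",
    "default_inhibitor_design",
]

TIMECOURSE_COLUMNS = (
    "time_min",
    "channel",
    "protocol",
    "replicate",
    "value_pct_of_added",
    "counts_bq",
)


@dataclass(frozen=True)
class TracerTimeCourse:
    """Observed or simulated measurement records.

    One row per (time, channel, protocol, replicate); values as percent of
    the tracer added to that channel.  ``counts_bq`` carries simulated (or
    measured) scintillation counts where available, else NaN.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in TIMECOURSE_COLUMNS[:5] if c not in df.columns]
        if missing:
            raise ValueError(f"missing time-course columns: {missing}")
        if "counts_bq" not in df.columns:
            df = df.assign(counts_bq=np.nan)
        df = df.loc[:, list(TIMECOURSE_COLUMNS)].reset_index(drop=True)
        if (df["value_pct_of_added"] < 0).any():
            raise ValueError("value_pct_of_added must be >= 0")
        key = df[["time_min", "channel", "protocol", "replicate"]]
        if key.duplicated().any():
            raise ValueError("(time, channel, protocol, replicate) must be unique")
        object.__setattr__(self, "frame", df)

    def select(self, channel: str | None = None, protocol=None, replicate=None) -> pd.DataFrame:
        df = self.frame
        if channel is not None:
            df = df[df["channel"] == channel]
        if protocol is not None:
            df = df[df["protocol"] == str(getattr(protocol, "value", protocol))]
        if replicate is not None:
            df = df[df["replicate"] == replicate]
        return df.sort_values("time_min")

    def mean_over_replicates(self, channel: str, protocol) -> pd.DataFrame:
        df = self.select(channel=channel, protocol=protocol)
        return df.groupby("time_min", as_index=False)["value_pct_of_added"].mean()


class NoiseKind(str, enum.Enum):
    NONE = "none"
    POISSON = "poisson"
    LOGNORMAL = "lognormal"


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model emulating scintillation counting.

    ``poisson``: a 100%-of-added signal corresponds to
    ``expected_counts_at_full_signal`` counts; each record's count is a
    Poisson draw at its expected count, rescaled back to percent.
    ``lognormal``: multiplicative ``exp(N(0, sigma))`` pipetting error.
    """

    kind: NoiseKind = NoiseKind.NONE
    expected_counts_at_full_signal: float = 1e4
    sigma: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", NoiseKind(self.kind))
        if self.expected_counts_at_full_signal <= 0:
            raise ValueError("expected_counts_at_full_signal must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind is not NoiseKind.NONE and self.seed is None:
            raise ValueError("a seed is mandatory for stochastic noise")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply_pct(self, values: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Return (noisy percent values, counts or NaN)."""
        values = np.asarray(values, dtype=float)
        if self.kind is NoiseKind.NONE:
            return values.copy(), np.full(values.shape, np.nan)
        if self.kind is NoiseKind.POISSON:
            expected = values * self.expected_counts_at_full_signal / 100.0
            counts = rng.poisson(expected).astype(float)
            return counts / self.expected_counts_at_full_signal * 100.0, counts
        noisy = values * np.exp(rng.normal(0.0, self.sigma, size=values.shape))
        return noisy, np.full(values.shape, np.nan)


def generate_pulse_chase(
    params: KineticParameters,
    design: ExperimentDesign,
    noise: NoiseModel = NoiseModel(),
) -> TracerTimeCourse:
    """Simulate a pulse-chase experiment and sample it like the bench does.

    Runs the compartment model, applies every wash/fixation protocol of the
    design at each sampling time and replicate, converts to percent of the
    tracer added to each channel, and applies the noise model.
    Deterministic given the noise seed.
    """
    if not design.additions:
        raise ValueError("the design must contain at least one tracer addition")
    traj = simulate(params, design)
    rng = noise.rng() if noise.kind is not NoiseKind.NONE else None

    rows: list[dict] = []
    for t in design.sampling_times:
        state = traj.state_at(t)
        for protocol in design.protocols:
            measured = apply_measurement(state, protocol, params)
            for ch in CHANNELS:
                added = design.added_molecules_per_cell(ch, t)
                pct = 0.0 if added == 0 else measured[ch] / added * 100.0
                for rep in range(1, design.replicates + 1):
                    rows.append(
                        {
                            "time_min": float(t),
                            "channel": ch,
                            "protocol": protocol.value,
                            "replicate": rep,
                            "value_pct_of_added": pct,
                        }
                    )
    df = pd.DataFrame(rows)
    if rng is not None:
        noisy, counts = noise.apply_pct(df["value_pct_of_added"].to_numpy(), rng)
        df["value_pct_of_added"] = noisy
        df["counts_bq"] = counts
    else:
        df["counts_bq"] = np.nan
    return TracerTimeCourse(df)


def generate_bioassay(
    ambient: float,
    velocity: float,
    added_concs,
    times,
    noise: NoiseModel = NoiseModel(),
) -> BioassaySeries:
    """Concentration-series bioassay under the turnover model.

    Per added concentration ``C_a`` and time ``t`` the taken-up fraction is
    ``1 - exp(-t v / (C_amb + C_a))``.  Noise is applied multiplicatively to
    the fraction and clipped into ``[0, 1)`` (fractions pushed to >= 1 are
    set to ``1 - 1e-6``; a rare event that slightly biases high-uptake
    points low).
    """
    if ambient <= 0 or velocity <= 0:
        raise ValueError("ambient and velocity must be > 0")
    added_concs = list(added_concs)
    if not added_concs:
        raise ValueError("added_concs must be non-empty")
    rng = noise.rng() if noise.kind is not NoiseKind.NONE else None
    entries = []
    for ca in added_concs:
        turnover = (ambient + ca) / velocity
        for t in times:
            f = -np.expm1(-t / turnover)
            if rng is not None:
                if noise.kind is NoiseKind.POISSON:
                    expected = f * noise.expected_counts_at_full_signal
                    f = rng.poisson(expected) / noise.expected_counts_at_full_signal
                else:
                    f = f * np.exp(rng.normal(0.0, noise.sigma))
                f = min(max(f, 0.0), 1.0 - 1e-6)
            entries.append(BioassayEntry(added_conc=ca, time_min=float(t), fraction_taken_up=float(f)))
    return BioassaySeries(tuple(entries))


def default_inhibitor_design(
    inhibitor: InhibitorEvent | None = None,
    cell_density: float = 1e9,
    tracer_conc: float = 1e-8,
    horizon_min: float = 30.0,
    step_min: float = 1.0,
) -> ExperimentDesign:
    """Short single-tracer accumulation experiment for inhibitor assays.

    Low cell density keeps seawater depletion negligible over the horizon,
    so the uninhibited accumulation is effectively linear in time — the
    basis of the delay estimate.  The inhibitor is added together with the
    tracer at t = 0, mirroring the bench protocol.
    """
    times = tuple(np.arange(step_min, horizon_min + step_min / 2, step_min))
    return ExperimentDesign(
        cell_density=cell_density,
        additions=(Addition(time_min=0.0, channel="P33", concentration=tracer_conc),),
        sampling_times=times,
        inhibitor_events=(inhibitor,) if inhibitor is not None else (),
        protocols=(Protocol.ASW,),
        replicates=1,
    )


def generate_inhibitor_experiment(
    params: KineticParameters,
    inhibitors,
    noise: NoiseModel = NoiseModel(),
    design_factory=default_inhibitor_design,
) -> dict[str, TracerTimeCourse]:
    """Paired control/treated accumulation time courses.

    Returns a mapping with a ``'control'`` entry plus one entry per
    inhibitor (keyed by its kind, e.g. ``'CCCP'``).  The effective
    inhibition delay is then computable as treated plateau divided by the
    control accumulation rate (see
    :func:`periphos.estimators.estimate_inhibition_delay`).
    """
    out: dict[str, TracerTimeCourse] = {
        "control": generate_pulse_chase(params, design_factory(None), noise)
    }
    for ev in inhibitors:
        if not isinstance(ev, InhibitorEvent):
            raise ValueError("inhibitors must be InhibitorEvent instances")
        key = ev.kind.value
        out[key] = generate_pulse_chase(params, design_factory(ev), noise)
    return out
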