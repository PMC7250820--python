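"""File formats and run configuration.

Fixed CSV dialect: comma delimiter, ``.`` decimal separator, LF line
endings, UTF-8, ``#`` comment lines.  Every file written by the package
starts with a provenance block of ``#`` comment lines (package version,
seed, config hash) so a run is reproducible from (config, seed).

Time-course CSV header (exact):

    time_min,channel,protocol,replicate,value_pct_of_added[,counts_bq]

Run configuration is a single YAML (JSON-compatible) key-value file with
sections ``geometry``, ``kinetics``, ``design`` and ``noise``; it is
validated before any computation and unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import SchemaError
from .geometry import CellGeometry, Shape
from .kinetics import (
    Addition,
    ExperimentDesign,
    InhibitorEvent,
    InhibitorKind,
    KineticParameters,
    Protocol,
)
from .synthetic import TIMECOURSE_COLUMNS, NoiseModel, TracerTimeCourse

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "RunConfig",
    "load_config",
    "provenance_lines",
]

_REQUIRED = list(TIMECOURSE_COLUMNS[:5])


def provenance_lines(seed: int | None = None, config: dict | None = None) -> list[str]:
    """Comment lines embedding version, seed and a config hash."""
    lines = [f"# periphos version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config sha256: {digest}")
    return lines


def write_timecourse(
    tc: TracerTimeCourse,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write a time course as CSV with a provenance comment header."""
    path = Path(path)
    df = tc.frame.copy()
    if df["counts_bq"].isna().all():
        df = df.drop(columns=["counts_bq"])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in provenance_lines(seed=seed, config=config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_timecourse(path: str | Path) -> TracerTimeCourse:
    """Read a time-course CSV, validating schema and values.

    Raises :class:`SchemaError` naming the missing column, or a row-level
    error with 1-based line numbers for non-numeric or negative values.
    """
    path = Path(path)
    # count comment lines for line-number reporting
    n_comments = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    df = pd.read_csv(path, comment="#", dtype=str)
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    extra = set(df.columns) - set(TIMECOURSE_COLUMNS)
    if extra:
        raise SchemaError(f"unknown columns: {sorted(extra)}")

    def line_no(i: int) -> int:  # 1-based file line of data row i
        return int(n_comments + 2 + i)

    numeric = {}
    for col in ("time_min", "value_pct_of_added", "replicate") + (
        ("counts_bq",) if "counts_bq" in df.columns else ()
    ):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            lines = [line_no(i) for i in np.flatnonzero(bad.to_numpy())]
            raise SchemaError(f"non-numeric {col!r} values at lines {lines}")
        numeric[col] = vals
    neg = numeric["value_pct_of_added"] < 0
    if neg.any():
        lines = [line_no(i) for i in np.flatnonzero(neg.to_numpy())]
        raise SchemaError(f"negative value_pct_of_added at lines {lines}")

    out = pd.DataFrame(
        {
            "time_min": numeric["time_min"].astype(float),
            "channel": df["channel"],
            "protocol": df["protocol"],
            "replicate": numeric["replicate"].astype(int),
            "value_pct_of_added": numeric["value_pct_of_added"].astype(float),
            "counts_bq": numeric.get("counts_bq", pd.Series(np.nan, index=df.index)).astype(float),
        }
    )
    return TracerTimeCourse(out)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    geometry: CellGeometry | None
    kinetics: KineticParameters
    design: ExperimentDesign
    noise: NoiseModel
    log_level: str = "INFO"
    raw: dict = dataclasses.field(default_factory=dict, repr=False)


def _build(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise SchemaError(f"unknown keys in {name!r} section: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"invalid {name!r} section: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError("config must be a mapping")
    known = {"geometry", "kinetics", "design", "noise", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config sections: {sorted(unknown)}")

    geometry = None
    if "geometry" in raw:
        g = dict(raw["geometry"])
        if "shape" in g:
            g["shape"] = Shape(g["shape"])
        geometry = _build(CellGeometry, g, "geometry")

    kinetics = _build(KineticParameters, dict(raw.get("kinetics", {})), "kinetics")

    if "design" not in raw:
        raise SchemaError("config must contain a 'design' section")
    d = dict(raw["design"])
    try:
        additions = tuple(
            Addition(
                time_min=a["time_min"],
                channel=a["channel"],
                concentration=a["concentration"],
                specific_activity=a.get("specific_activity"),
            )
            for a in d.pop("additions", [])
        )
        inhibitors = tuple(
            InhibitorEvent(
                time_min=e["time_min"],
                kind=InhibitorKind(e["kind"]),
                factor=e.get("factor"),
            )
            for e in d.pop("inhibitor_events", [])
        )
        protocols = tuple(Protocol(p) for p in d.pop("protocols", ["ASW", "DW", "PFA", "TCA"]))
        light = d.pop("light_schedule", None)
        design = ExperimentDesign(
            additions=additions,
            inhibitor_events=inhibitors,
            protocols=protocols,
            light_schedule=tuple(tuple(iv) for iv in light) if light is not None else None,
            sampling_times=tuple(d.pop("sampling_times")),
            cell_density=d.pop("cell_density"),
            replicates=d.pop("replicates", 2),
        )
    except KeyError as exc:
        raise SchemaError(f"design section missing key {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"invalid design section: {exc}") from exc
    if d:
        raise SchemaError(f"unknown keys in 'design' section: {sorted(d)}")

    noise = _build(NoiseModel, dict(raw.get("noise", {})), "noise")
    level = raw.get("log_level", "INFO")
    return RunConfig(geometry=geometry, kinetics=kinetics, design=design,
                     noise=noise, log_level=level, raw=raw)
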