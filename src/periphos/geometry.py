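"""Cell geometry, periplasm capacity, and concentration/osmolarity arithmetic.

The periplasm of a Gram-negative marine bacterium is a thin aqueous shell
(depth ~1e-8 m) between the outer and plasma membranes.  Its tiny volume
(~2e-17 l for a *Synechococcus*-sized coccus) is what makes periplasmic
phosphate budgets so counter-intuitive: a handful of free P_i molecules
already exceeds the ~1e-7 mol l^-1 half-saturation of the high-affinity
PstSCAB import system, and millions of accumulated molecules correspond to
tenths of mol l^-1.  The functions here provide the exact shell/surface
arithmetic and the packing / concentration / osmolarity conversions needed
to test whether protein binding (PstS subunits) could plausibly hold the
accumulated P_i.

Raw operations never round; :func:`paper_style` formats a value at 1 and 2
significant figures for report-style display.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .constants import AVOGADRO, NM3_TO_L, UM3_TO_L, UM_TO_M

__all__ = [
    "Shape",
    "CellGeometry",
    "PhysicalConstants",
    "ellipsoid_volume",
    "periplasm_shell_volume",
    "surface_and_volume",
    "molecules_to_concentration",
    "packing_capacity",
    "deficit_ratio",
    "osmolarity_increment",
    "paper_style",
]


class Shape(str, enum.Enum):
    """Cell shape for closed-form geometry."""

    SPHERE = "sphere"
    SPHEROCYLINDER = "spherocylinder"


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants (immutable)."""

    avogadro: float = AVOGADRO
    phosphorus_molar_mass: float = 30.974


@dataclass(frozen=True)
class CellGeometry:
    """Shape and dimensions of a cell plus periplasm depth.

    Parameters
    ----------
    shape
        ``sphere`` or ``spherocylinder`` (capsule).
    diameter_um
        Cell diameter in micrometres.
    total_length_um
        Tip-to-tip length in micrometres; equals the diameter for spheres.
        For a spherocylinder the cylindrical section has length
        ``total_length_um - diameter_um``.
    periplasm_depth_m
        Periplasm depth in metres (default 1e-8 m).
    """

    shape: Shape
    diameter_um: float
    total_length_um: float | None = None
    periplasm_depth_m: float = 1e-8

    def __post_init__(self) -> None:
        if self.total_length_um is None:
            object.__setattr__(self, "total_length_um", self.diameter_um)
        if self.diameter_um <= 0:
            raise ValueError(f"diameter_um must be > 0, got {self.diameter_um}")
        if self.total_length_um < self.diameter_um:
            raise ValueError(
                "total_length_um must be >= diameter_um "
                f"({self.total_length_um} < {self.diameter_um})"
            )
        if self.shape is Shape.SPHERE and self.total_length_um != self.diameter_um:
            raise ValueError("a sphere must have total_length_um == diameter_um")
        if self.periplasm_depth_m < 0:
            raise ValueError("periplasm_depth_m must be >= 0")
        if self.periplasm_depth_m >= self.diameter_um * UM_TO_M / 2:
            raise ValueError("periplasm_depth_m must be < cell radius")

    @property
    def depth_um(self) -> float:
        return self.periplasm_depth_m / UM_TO_M


def ellipsoid_volume(d1_nm: float, d2_nm: float, d3_nm: float) -> float:
    """Volume in litres of an ellipsoid given its three axis *diameters* in nm.

    ``V = pi/6 * d1 * d2 * d3``.  For the PstS phosphate-binding subunit
    (3.5 x 4 x 7 nm) this gives ~5.1e-23 l.
    """
    if d1_nm <= 0 or d2_nm <= 0 or d3_nm <= 0:
        raise ValueError("all ellipsoid diameters must be > 0")
    return math.pi / 6.0 * d1_nm * d2_nm * d3_nm * NM3_TO_L


def _sphere_volume_um3(d_um: float) -> float:
    return math.pi / 6.0 * d_um**3


def _spherocylinder_volume_um3(d_um: float, total_length_um: float) -> float:
    h = total_length_um - d_um  # cylindrical section
    return math.pi / 4.0 * d_um**2 * h + math.pi / 6.0 * d_um**3


def _body_volume_um3(shape: Shape, d_um: float, total_length_um: float) -> float:
    if shape is Shape.SPHERE:
        return _sphere_volume_um3(d_um)
    return _spherocylinder_volume_um3(d_um, total_length_um)


def surface_and_volume(geom: CellGeometry) -> tuple[float, float, float]:
    """Closed-form surface area (um^2), volume (um^3) and their ratio (um^-1).

    Sphere: ``A = pi d^2``, ``V = pi/6 d^3``.  Spherocylinder with tip-to-tip
    length ``L`` and cylinder length ``h = L - d``: ``A = pi d h + pi d^2``,
    ``V = pi/4 d^2 h + pi/6 d^3``.  A spherocylinder with ``L = d``
    degenerates to the sphere.
    """
    d = geom.diameter_um
    ltot = geom.total_length_um
    if geom.shape is Shape.SPHERE:
        area = math.pi * d**2
    else:
        h = ltot - d
        area = math.pi * d * h + math.pi * d**2
    vol = _body_volume_um3(geom.shape, d, ltot)
    return area, vol, area / vol


def periplasm_shell_volume(geom: CellGeometry) -> float:
    """Exact outer-minus-inner volume (litres) of the periplasmic shell.

    The shell of thickness ``t = periplasm_depth_m`` lies immediately inside
    the outer surface; the inner body is the same shape shrunk by ``2t`` in
    diameter (and total length, for spherocylinders).  Converges to
    ``surface_area * t`` in the thin-shell limit.
    """
    t_um = geom.depth_um
    d = geom.diameter_um
    ltot = geom.total_length_um
    if t_um == 0:
        return 0.0
    if t_um >= d / 2:
        raise ValueError("periplasm depth must be smaller than the cell radius")
    outer = _body_volume_um3(geom.shape, d, ltot)
    inner = _body_volume_um3(geom.shape, d - 2 * t_um, ltot - 2 * t_um)
    return (outer - inner) * UM3_TO_L


def molecules_to_concentration(n_molecules: float, volume_l: float) -> float:
    """Concentration (mol l^-1) of ``n`` molecules dissolved in ``volume_l``."""
    if n_molecules < 0:
        raise ValueError("molecule count must be >= 0")
    if volume_l <= 0:
        raise ValueError("volume must be > 0")
    return n_molecules / (AVOGADRO * volume_l)


def packing_capacity(container_volume_l: float, unit_volume_l: float) -> int:
    """Number of rigid units of ``unit_volume_l`` fitting by volume alone.

    ``floor(container / unit)`` — an upper bound ignoring packing geometry,
    which is the generous assumption when asking whether enough PstS
    subunits could even exist in the periplasm.
    """
    if container_volume_l <= 0:
        raise ValueError("container volume must be > 0")
    if unit_volume_l <= 0:
        raise ValueError("unit volume must be > 0")
    return math.floor(container_volume_l / unit_volume_l)


def deficit_ratio(required: float, capacity: float) -> float:
    """Fold by which the required count exceeds the capacity."""
    if required < 0:
        raise ValueError("required count must be >= 0")
    if capacity <= 0:
        raise ValueError("capacity must be > 0")
    return required / capacity


def osmolarity_increment(salt_conc_mol_per_l: float, particles_per_formula: float = 1) -> float:
    """Osmolarity increase (osmol l^-1) from adding a salt.

    A neutral ion pair (the phosphatation hypothesis: P_i anion paired with
    a chemiosmotic cation) contributes one osmotically active particle per
    formula unit.
    """
    if salt_conc_mol_per_l < 0 or particles_per_formula < 0:
        raise ValueError("inputs must be >= 0")
    return salt_conc_mol_per_l * particles_per_formula


def paper_style(value: float) -> dict[str, float]:
    """Report a value at full precision and rounded to 1 and 2 sig. figures."""
    def round_sf(x: float, sf: int) -> float:
        if x == 0:
            return 0.0
        return round(x, -int(math.floor(math.log10(abs(x)))) + (sf - 1))

    return {"full": value, "sf2": round_sf(value, 2), "sf1": round_sf(value, 1)}
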