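"""Diffusion-limited and porin-restricted P_i clearance theory.

For a perfectly absorbing sphere of radius ``a`` in a medium with solute
diffusivity ``D``, the maximal volume of water a cell can clear of solute per
unit time is ``4 pi D a`` (the diffusion-limited ceiling).  When uptake is
restricted to ``N`` absorbing porin patches of radius ``s`` on an otherwise
reflecting surface, the classic disc-absorber result gives

    CL = 4 pi D a * N s / (N s + pi a),

which saturates towards the full diffusion limit once ``N s >> pi a`` — a
surprisingly small number of patches suffices.  Clearance is reported in
l min^-1 throughout.

The default phosphate diffusivity in seawater, ``D = 7e-10 m^2 s^-1``, is a
standard literature magnitude for orthophosphate at ocean temperature; every
ratio computed here accepts ``D`` as input.  Non-spherical cells are handled
by an equivalent-sphere radius of equal surface area (an approximation;
exact capacitances of spherocylinders are out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import AVOGADRO, M3_PER_S_TO_L_PER_MIN

__all__ = [
    "DEFAULT_PHOSPHATE_DIFFUSIVITY",
    "DiffusionContext",
    "max_clearance_sphere",
    "porin_restricted_clearance",
    "clearance_deficit",
    "biovolume_specific_clearance",
    "quota_doubling_time",
    "equivalent_sphere_radius",
]

#: Orthophosphate diffusivity in seawater, m^2 s^-1 (literature magnitude).
DEFAULT_PHOSPHATE_DIFFUSIVITY: float = 7e-10


@dataclass(frozen=True)
class DiffusionContext:
    """Physical context for clearance-rate theory.

    Parameters
    ----------
    diffusivity
        Solute diffusivity in seawater, m^2 s^-1.
    cell_radius
        Cell radius, m.
    porin_count
        Number of solute-permeable porin patches (0 means none).
    porin_radius
        Patch radius, m.  Required positive when ``porin_count > 0``.
    """

    diffusivity: float = DEFAULT_PHOSPHATE_DIFFUSIVITY
    cell_radius: float = 0.5e-6
    porin_count: int = 0
    porin_radius: float = 1e-9

    def __post_init__(self) -> None:
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be > 0")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be > 0")
        if self.porin_count < 0:
            raise ValueError("porin_count must be >= 0")
        if self.porin_count > 0 and self.porin_radius <= 0:
            raise ValueError("porin_radius must be > 0 when porin_count > 0")


def max_clearance_sphere(ctx: DiffusionContext) -> float:
    """Diffusion-limited clearance ``4 pi D a`` of a perfect sphere, l min^-1."""
    return 4.0 * math.pi * ctx.diffusivity * ctx.cell_radius * M3_PER_S_TO_L_PER_MIN


def porin_restricted_clearance(ctx: DiffusionContext) -> float:
    """Clearance of a sphere absorbing only through ``N`` porin discs, l min^-1.

    ``4 pi D a * N s / (N s + pi a)``; 0 when ``N = 0``, exactly half the
    diffusion limit when ``N s = pi a``, and the full limit as ``N -> inf``.
    """
    ns = ctx.porin_count * ctx.porin_radius
    if ns == 0:
        return 0.0
    return max_clearance_sphere(ctx) * ns / (ns + math.pi * ctx.cell_radius)


def clearance_deficit(measured_cl: float, ctx: DiffusionContext) -> float:
    """Fold by which a measured clearance falls below the diffusion limit."""
    if measured_cl <= 0:
        raise ValueError("measured clearance must be > 0")
    return max_clearance_sphere(ctx) / measured_cl


def biovolume_specific_clearance(cl: float, cell_volume_l: float) -> float:
    """Clearance expressed as cell volumes of water cleared per minute."""
    if cell_volume_l <= 0:
        raise ValueError("cell volume must be > 0")
    if cl < 0:
        raise ValueError("clearance must be >= 0")
    return cl / cell_volume_l


def quota_doubling_time(cl: float, conc_mol_per_l: float, quota_atoms: float) -> float:
    """Minutes for a cell to accumulate its own P quota at clearance ``cl``.

    In the unsaturated regime the accumulation rate is
    ``cl * conc * N_A`` atoms min^-1, so the doubling time of the cellular P
    content is ``quota / (cl * conc * N_A)``.
    """
    if cl <= 0 or conc_mol_per_l <= 0 or quota_atoms <= 0:
        raise ValueError("cl, concentration and quota must all be > 0")
    return quota_atoms / (cl * conc_mol_per_l * AVOGADRO)


def equivalent_sphere_radius(surface_area_um2: float) -> float:
    """Radius (m) of the sphere with the given surface area (um^2)."""
    if surface_area_um2 <= 0:
        raise ValueError("surface area must be > 0")
    r_um = math.sqrt(surface_area_um2 / (4.0 * math.pi))
    return r_um * 1e-6
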