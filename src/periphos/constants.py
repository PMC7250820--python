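"""Physical constants and unit conversions used throughout the package.

Unit conventions (fixed, no auto-detection):

* time in minutes,
* seawater concentrations in mol l^-1,
* per-cell amounts in molecules (atoms of P),
* cell lengths in micrometres, protein dimensions in nanometres,
  membrane/periplasm depths in metres,
* all volumes returned in litres,
* clearance rates in l cell^-1 min^-1.
"""

from __future__ import annotations

#: Avogadro constant, exact (molecules per mol).
AVOGADRO: float = 6.02214076e23

#: Molar mass of phosphorus, g mol^-1.
PHOSPHORUS_MOLAR_MASS: float = 30.974

# --- volume conversions to litres -------------------------------------------
NM3_TO_L: float = 1e-24   # 1 nm^3
UM3_TO_L: float = 1e-15   # 1 um^3
M3_TO_L: float = 1e3      # 1 m^3

# --- length conversions ------------------------------------------------------
UM_TO_M: float = 1e-6
NM_TO_M: float = 1e-9

#: m^3 s^-1 -> l min^-1 (x1000 litres per m^3, x60 s per min)
M3_PER_S_TO_L_PER_MIN: float = M3_TO_L * 60.0


def molecules_per_cell(concentration_mol_per_l: float, cell_density_per_l: float) -> float:
    """Molecules of solute available per cell at a given seawater concentration.

    This is the natural per-cell bookkeeping unit for tracer budgets:
    ``C * N_A / rho``.
    """
    return concentration_mol_per_l * AVOGADRO / cell_density_per_l
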