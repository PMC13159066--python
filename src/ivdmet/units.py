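"""Unit conventions and conversions.

Canonical internal units: length mm, time s, concentration mM.
Cellular metabolic rates are measured in nmol / million cells / h and
converted to volumetric rates (mM/s) exactly once, here.
"""

from __future__ import annotations

import numpy as np

#: Henry's-law constant for oxygen in culture medium at 37 degC, atm/M.
HENRY_O2_ATM_PER_M = 929.6

#: Dissolved-oxygen anchor concentrations (mM) at the 1% and 5% partial
#: pressures used for the kinetic parameter sets (0.01 and 0.05 atm through
#: Henry's law, at the printed rounding).
O2_CONC_1PCT_MM = 0.011
O2_CONC_5PCT_MM = 0.054

#: nmol/(million cells)/h x (million cells)/mL  ->  mM/s divisor.
#: nmol/mL == uM; /3600 for per-second; /1000 for uM -> mM.
RATE_TO_MM_PER_S = 3.6e6

#: m^2/s -> mm^2/s
M2_TO_MM2 = 1.0e6


def po2_to_concentration(partial_pressure_atm, henry_constant=HENRY_O2_ATM_PER_M):
    """Convert an oxygen partial pressure (atm) to dissolved concentration (mM).

    c [mM] = 1000 * P [atm] / H [atm/M].
    """
    if henry_constant <= 0:
        raise ValueError(f"Henry constant must be positive, got {henry_constant}")
    p = np.asarray(partial_pressure_atm, dtype=float)
    if np.any(p < 0):
        raise ValueError("partial pressure must be nonnegative")
    out = 1000.0 * p / henry_constant
    return out.item() if np.isscalar(partial_pressure_atm) else out


def cellular_to_volumetric(rate_nmol_per_mcells_h, cell_density_mcells_per_ml):
    """nmol/million cells/h at a given cell density -> volumetric mM/s."""
    return rate_nmol_per_mcells_h * cell_density_mcells_per_ml / RATE_TO_MM_PER_S
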