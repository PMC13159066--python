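"""Post-processing of steady-state field solutions.

Volume-weighted regional statistics, saturation-normalised availability
summaries, and flat headline tables. Volumetric weights are the cell
volumes 2*pi*r*dr*dz of the axisymmetric grid; extrema are taken over
interior cell centres (boundary faces sit at the prescribed media values by
construction and are not model predictions).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .transport import AxiGrid, FieldSolution, Scenario

__all__ = [
    "summarize",
    "normalize",
    "compare_table",
    "headline",
]

SOLUTES = ("glucose", "lactate", "oxygen")


def _region_stats(values: np.ndarray, vol: np.ndarray, mask: np.ndarray) -> dict:
    v = values[mask]
    w = vol[mask]
    integral = float(np.sum(v * w))
    volume = float(np.sum(w))
    return {
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": integral / volume,
        "integral": integral,
        "volume": volume,
    }


def summarize(solution: FieldSolution, grid: AxiGrid) -> pd.DataFrame:
    """Per-region (and ALL) volume-weighted statistics of one solution.

    Concentrations in mM (integrals mM*mm^3); ATP synthesis in uM/s
    (integral uM/s*mm^3). Refuses non-converged solutions.
    """
    if not solution.converged:
        raise ValueError("refusing to summarise a non-converged solution")
    vol = grid.cell_volumes
    masks = {r: grid.region_mask(r) for r in ("NP", "AF", "CEP")}
    masks["ALL"] = np.ones(grid.shape, dtype=bool)
    q_atp_um = solution.q_atp * 1e3  # mM/s -> uM/s

    rows = []
    for region, mask in masks.items():
        row = {"scenario": solution.scenario.name, "region": region}
        for solute in SOLUTES:
            st = _region_stats(getattr(solution, solute), vol, mask)
            row[f"{solute}_min_mM"] = st["min"]
            row[f"{solute}_max_mM"] = st["max"]
            row[f"{solute}_mean_mM"] = st["mean"]
            row[f"{solute}_integral_mM_mm3"] = st["integral"]
        st = _region_stats(q_atp_um, vol, mask)
        row["qatp_max_uM_per_s"] = st["max"]
        row["qatp_integral_uM_per_s_mm3"] = st["integral"]
        row["volume_mm3"] = st["volume"]
        rows.append(row)
    return pd.DataFrame(rows)


def headline(solution: FieldSolution, grid: AxiGrid) -> dict:
    """Global interior extrema: the per-scenario headline numbers."""
    if not solution.converged:
        raise ValueError("refusing to summarise a non-converged solution")
    return {
        "scenario": solution.scenario.name,
        "min_glucose_mM": float(solution.glucose.min()),
        "max_lactate_mM": float(solution.lactate.max()),
        "min_oxygen_uM": float(solution.oxygen.min() * 1e3),
        "max_atp_uM_per_s": float(solution.q_atp.max() * 1e3),
    }


def normalize(
    summaries: Mapping[str, pd.DataFrame],
    reference_scenario: Scenario,
    reference: str = "physiological",
    atp_reference: str = "global",
) -> pd.DataFrame:
    """Saturation-normalised availability per region and scenario.

    Solute fractions divide the volumetric integral by (reference boundary
    concentration x region volume), so a disc fully equilibrated with the
    physiological media scores 1; lactate, which accumulates above its
    boundary value, may exceed 1. The ATP fraction divides by (maximum ATP
    synthesis rate under the reference scenario x region volume); with
    ``atp_reference='per_region'`` each region uses its own reference
    maximum instead of the global one.
    """
    if reference not in summaries:
        raise ValueError(f"reference scenario {reference!r} not among summaries")
    if atp_reference not in ("global", "per_region"):
        raise ValueError("atp_reference must be 'global' or 'per_region'")
    ref = summaries[reference].set_index("region")
    c0 = {
        "glucose": reference_scenario.c0_glucose,
        "lactate": reference_scenario.c0_lactate,
        "oxygen": reference_scenario.c0_oxygen,
    }
    if min(c0.values()) <= 0:
        raise ValueError("reference boundary concentrations must be positive")
    atp_max_global = float(ref.loc["ALL", "qatp_max_uM_per_s"])
    if atp_max_global <= 0:
        raise ValueError("reference maximum ATP synthesis rate is zero")

    rows = []
    for name, df in summaries.items():
        for _, row in df.iterrows():
            region = row["region"]
            vol = row["volume_mm3"]
            out = {"scenario": name, "region": region}
            for solute in SOLUTES:
                out[f"{solute}_availability"] = (
                    row[f"{solute}_integral_mM_mm3"] / (c0[solute] * vol)
                )
            atp_max = (
                float(ref.loc[region, "qatp_max_uM_per_s"])
                if atp_reference == "per_region"
                else atp_max_global
            )
            out["atp_availability"] = row["qatp_integral_uM_per_s_mm3"] / (
                atp_max * vol
            )
            rows.append(out)
    return pd.DataFrame(rows)


def compare_table(summaries: Mapping[str, pd.DataFrame],
                  grids: Mapping[str, AxiGrid] | None = None) -> pd.DataFrame:
    """Flat table of headline extrema, one row per (scenario, quantity)."""
    rows = []
    for name, df in summaries.items():
        g = df.set_index("region").loc["ALL"]
        for quantity, value, unit in [
            ("min_glucose", g["glucose_min_mM"], "mM"),
            ("max_lactate", g["lactate_max_mM"], "mM"),
            ("min_oxygen", g["oxygen_min_mM"] * 1e3, "uM"),
            ("max_atp", g["qatp_max_uM_per_s"], "uM_per_s"),
        ]:
            rows.append(
                {"scenario": name, "quantity": quantity,
                 "value": float(value), "unit": unit}
            )
    return pd.DataFrame(rows, columns=["scenario", "quantity", "value", "unit"])
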