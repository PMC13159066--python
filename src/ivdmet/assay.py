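"""Quantification of explant culture metabolic rates.

Minced disc tissue is cultured in a known media volume and glucose/lactate
concentrations are read hourly. Tissue volume comes from Archimedes'
principle (wet minus buoyant weight over the PBS density); rates are

    rate = dc * V_media / (dt * rho_cell * V_tissue)

normalised to the regional cell count (rho_cell in million cells/mL of
tissue), reported in nmol per million cells per hour. Glucose consumption
(GCR) and lactate production (LPR) are both positive under normal biology.
Steady-state rates average the hourly interval rates inside a 2-5 h window;
replicate wells are then averaged within each animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CultureWell",
    "AssayConstants",
    "RateResult",
    "compute_tissue_volume",
    "interval_rates",
    "steady_state_rates",
    "aggregate_by_animal",
    "quantify_cohort",
    "read_cohort",
    "rates_to_frame",
]

VALID_REGIONS = ("NP", "AF", "CEP")

#: Region-specific cell densities (million cells / mL tissue) from rat disc
#: histology; used to convert tissue volume to cell number.
DEFAULT_CELL_DENSITY = {"NP": 35.71, "AF": 53.57, "CEP": 78.57}


class InvalidMeasurementError(ValueError):
    """A well's raw measurements are physically inconsistent."""


@dataclass(frozen=True)
class AssayConstants:
    """Fixed assay parameters.

    rho_pbs : density of the 10x PBS bath (g/cm^3).
    rho_cell : region -> cell density (million cells/mL tissue).
    window : (start_h, end_h) for steady-state averaging.
    """

    rho_pbs: float = 1.07
    rho_cell: dict = field(default_factory=lambda: dict(DEFAULT_CELL_DENSITY))
    window: tuple = (2.0, 5.0)

    def __post_init__(self):
        if self.rho_pbs <= 1.0:
            raise ValueError("rho_pbs must exceed 1.0 g/cm^3")
        if any(v <= 0 for v in self.rho_cell.values()):
            raise ValueError("cell densities must be positive")
        lo, hi = self.window
        if not 0 <= lo < hi:
            raise ValueError("window must satisfy 0 <= start < end")


@dataclass(frozen=True)
class CultureWell:
    """One culture well: tissue metadata plus hourly concentration series."""

    animal_id: str
    region: str
    treatment: str
    wet_weight: float  # g
    buoyant_weight: float  # g
    media_volume: float  # mL
    times: tuple  # h, strictly increasing, first = 0
    glucose_series: tuple  # mM
    lactate_series: tuple  # mM
    well_id: str = ""

    def __post_init__(self):
        if self.region not in VALID_REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.buoyant_weight < 0 or self.buoyant_weight > self.wet_weight:
            raise InvalidMeasurementError(
                f"well {self.well_id or self.animal_id}: buoyant weight "
                f"{self.buoyant_weight} g inconsistent with wet weight "
                f"{self.wet_weight} g"
            )
        if self.media_volume <= 0:
            raise ValueError("media volume must be positive")
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.glucose_series, dtype=float)
        l = np.asarray(self.lactate_series, dtype=float)
        if not (len(t) == len(g) == len(l)):
            raise ValueError("times and concentration series must align")
        if len(t) and t[0] != 0:
            raise ValueError("time series must start at 0 h")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(g < 0) or np.any(l < 0):
            raise ValueError("concentrations must be nonnegative")


@dataclass(frozen=True)
class RateResult:
    """Steady-state rates for one well (nmol/million cells/h)."""

    animal_id: str
    region: str
    treatment: str
    gcr: float
    lpr: float
    ratio: float  # LPR:GCR; NaN when GCR <= 0 (flagged, never fabricated)
    n_intervals: int
    well_id: str = ""

    @property
    def ratio_defined(self) -> bool:
        return not np.isnan(self.ratio)


def compute_tissue_volume(wet_weight: float, buoyant_weight: float,
                          rho_pbs: float = 1.07, well_id: str = "") -> float:
    """Tissue volume (cm^3) by Archimedes' principle."""
    if rho_pbs <= 0:
        raise ValueError("rho_pbs must be positive")
    if buoyant_weight < 0 or buoyant_weight > wet_weight:
        raise InvalidMeasurementError(
            f"well {well_id or '<unnamed>'}: buoyant weight {buoyant_weight} g "
            f"exceeds wet weight {wet_weight} g"
        )
    return (wet_weight - buoyant_weight) / rho_pbs


def _cells(well: CultureWell, constants: AssayConstants) -> float:
    """Million cells in the well's tissue piece."""
    v_tissue = compute_tissue_volume(
        well.wet_weight, well.buoyant_weight, constants.rho_pbs, well.well_id
    )
    if v_tissue <= 0:
        raise InvalidMeasurementError(
            f"well {well.well_id or well.animal_id}: zero tissue volume"
        )
    return constants.rho_cell[well.region] * v_tissue


def interval_rates(well: CultureWell, constants: AssayConstants | None = None):
    """Per-interval (midpoint_h, gcr, lpr) for consecutive reading pairs.

    gcr_k = (c_glu(t_k) - c_glu(t_k+1)) * V_media * 1000 / (dt * cells);
    lpr_k with the sign flipped (production). Units nmol/million cells/h.
    """
    constants = constants or AssayConstants()
    t = np.asarray(well.times, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 time points")
    cells = _cells(well, constants)
    g = np.asarray(well.glucose_series, dtype=float)
    l = np.asarray(well.lactate_series, dtype=float)
    dt = np.diff(t)
    gcr = (g[:-1] - g[1:]) * well.media_volume * 1000.0 / (dt * cells)
    lpr = (l[1:] - l[:-1]) * well.media_volume * 1000.0 / (dt * cells)
    mid = (t[:-1] + t[1:]) / 2
    return list(zip(mid.tolist(), gcr.tolist(), lpr.tolist()))


def steady_state_rates(
    well: CultureWell,
    constants: AssayConstants | None = None,
    method: str = "interval_mean",
) -> RateResult:
    """Steady-state GCR/LPR averaged over the 2-5 h window.

    ``interval_mean`` (default) averages the hourly interval rates whose
    endpoints both lie inside the window; ``regression`` uses the slope of a
    least-squares line through the readings inside the window instead.
    """
    constants = constants or AssayConstants()
    t = np.asarray(well.times, dtype=float)
    lo, hi = constants.window
    tol = 1e-9

    if method == "interval_mean":
        rates = interval_rates(well, constants)
        inside = [
            (g, l)
            for (t0, t1), (_, g, l) in zip(zip(t[:-1], t[1:]), rates)
            if t0 >= lo - tol and t1 <= hi + tol
        ]
        if not inside:
            raise ValueError(
                f"no sampling interval lies inside the window [{lo}, {hi}] h"
            )
        gcr = float(np.mean([g for g, _ in inside]))
        lpr = float(np.mean([l for _, l in inside]))
        n = len(inside)
    elif method == "regression":
        mask = (t >= lo - tol) & (t <= hi + tol)
        if mask.sum() < 2:
            raise ValueError("need >= 2 readings inside the window for regression")
        cells = _cells(well, constants)
        g = np.asarray(well.glucose_series, dtype=float)[mask]
        l = np.asarray(well.lactate_series, dtype=float)[mask]
        slope_g = np.polyfit(t[mask], g, 1)[0]
        slope_l = np.polyfit(t[mask], l, 1)[0]
        gcr = float(-slope_g * well.media_volume * 1000.0 / cells)
        lpr = float(slope_l * well.media_volume * 1000.0 / cells)
        n = int(mask.sum()) - 1
    else:
        raise ValueError(f"unknown method {method!r}")

    ratio = lpr / gcr if gcr > 0 else float("nan")
    return RateResult(
        well.animal_id, well.region, well.treatment, gcr, lpr, ratio, n,
        well.well_id,
    )


def rates_to_frame(results: Sequence[RateResult]) -> pd.DataFrame:
    """Tidy per-well rate table."""
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in results],
            "region": [r.region for r in results],
            "treatment": [r.treatment for r in results],
            "well_id": [r.well_id for r in results],
            "gcr_nmol_per_Mcells_h": [r.gcr for r in results],
            "lpr_nmol_per_Mcells_h": [r.lpr for r in results],
            "ratio_lpr_gcr": [r.ratio for r in results],
            "n_intervals": [r.n_intervals for r in results],
        }
    )


def aggregate_by_animal(results: Sequence[RateResult]) -> pd.DataFrame:
    """Average replicate wells within each (animal, region, treatment).

    GCR, LPR, and the per-well ratios are each averaged arithmetically (the
    reported ratio is the mean of ratios, not the ratio of means).
    """
    if not results:
        raise ValueError("no results to aggregate")
    for r in results:
        if r.region not in VALID_REGIONS:
            raise ValueError(f"unknown region {r.region!r}")
    df = rates_to_frame(results)
    out = (
        df.groupby(["animal_id", "region", "treatment"], as_index=False)
        .agg(
            gcr_nmol_per_Mcells_h=("gcr_nmol_per_Mcells_h", "mean"),
            lpr_nmol_per_Mcells_h=("lpr_nmol_per_Mcells_h", "mean"),
            ratio_lpr_gcr=("ratio_lpr_gcr", "mean"),
            n_wells=("well_id", "size"),
        )
    )
    return out


# ---------------------------------------------------------------------------
# CSV interfaces

MEASUREMENT_COLUMNS = ["well_id", "time_h", "glucose_mM", "lactate_mM"]
WELL_COLUMNS = [
    "well_id", "animal_id", "region", "treatment",
    "wet_weight_g", "buoyant_weight_g", "media_volume_mL",
]


def read_cohort(measurements, wells) -> list:
    """Assemble CultureWells from two long-format tables (paths or frames).

    ``measurements``: one row per well per time point (well_id, time_h,
    glucose_mM, lactate_mM). ``wells``: one row per well with tissue weights
    and media volume.
    """
    meas = measurements if isinstance(measurements, pd.DataFrame) else pd.read_csv(measurements)
    meta = wells if isinstance(wells, pd.DataFrame) else pd.read_csv(wells)
    for col in MEASUREMENT_COLUMNS:
        if col not in meas.columns:
            raise ValueError(f"measurements table missing column {col!r}")
    for col in WELL_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"well table missing column {col!r}")
    out = []
    grouped = meas.sort_values("time_h").groupby("well_id")
    for row in meta.itertuples(index=False):
        try:
            series = grouped.get_group(row.well_id)
        except KeyError:
            raise ValueError(f"no measurements for well {row.well_id!r}") from None
        out.append(
            CultureWell(
                animal_id=str(row.animal_id),
                region=str(row.region),
                treatment=str(row.treatment),
                wet_weight=float(row.wet_weight_g),
                buoyant_weight=float(row.buoyant_weight_g),
                media_volume=float(row.media_volume_mL),
                times=tuple(series["time_h"]),
                glucose_series=tuple(series["glucose_mM"]),
                lactate_series=tuple(series["lactate_mM"]),
                well_id=str(row.well_id),
            )
        )
    return out


def quantify_cohort(
    measurements,
    wells,
    constants: AssayConstants | None = None,
    method: str = "interval_mean",
):
    """End-to-end: tables -> (per-well rates frame, per-animal means frame)."""
    cohort = read_cohort(measurements, wells)
    results = [steady_state_rates(w, constants, method) for w in cohort]
    return rates_to_frame(results), aggregate_by_animal(results)
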