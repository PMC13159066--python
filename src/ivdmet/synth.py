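"""Synthetic culture-assay and kinetics datasets with known ground truth.

The cohort generator emulates the explant assay design: minced tissue
(50-100 mg nominal; defaults trimmed to 50-70 mg so the steepest default
condition keeps media glucose above the 0.5 mM viability floor under the
generator's constant-rate trajectories), 600 uL media for NP wells and
800 uL for AF/CEP, hourly sampling 0-5 h after preconditioning, duplicate
or triplicate wells per region per animal, and additive i.i.d. Gaussian
measurement noise on every concentration reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assay import DEFAULT_CELL_DENSITY, CultureWell
from .kinetics import MMPair

__all__ = [
    "TreatmentCondition",
    "AssayDesign",
    "GroundTruth",
    "default_ground_truth",
    "generate_cohort",
    "generate_mm_dataset",
]

#: Media glucose below this is treated as loss of viability; designs whose
#: noiseless trajectories would cross it are refused.
GLUCOSE_VIABILITY_FLOOR_MM = 0.5

#: Tissue density assumed when back-computing buoyant weights (g/cm^3);
#: generator-internal only — the estimator consumes the emitted weights.
TISSUE_DENSITY = 1.10

RHO_PBS = 1.07


@dataclass(frozen=True)
class TreatmentCondition:
    """Culture-media condition for one treatment arm."""

    glucose_mM: float
    o2_pct: float
    cse: bool = False


DEFAULT_TREATMENTS = {
    "control": TreatmentCondition(5.5, 5.0, False),
    "cse": TreatmentCondition(5.5, 5.0, True),
    "low_nutrient": TreatmentCondition(1.5, 1.0, False),
}


@dataclass(frozen=True)
class AssayDesign:
    """Cohort layout and sampling scheme."""

    n_animals: int = 8
    regions: tuple = ("NP", "AF", "CEP")
    treatments: dict = field(default_factory=lambda: dict(DEFAULT_TREATMENTS))
    replicates: int = 2
    media_volume_ml: dict = field(
        default_factory=lambda: {"NP": 0.6, "AF": 0.8, "CEP": 0.8}
    )
    tissue_mass_range_g: tuple = (0.05, 0.07)
    sample_times_h: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    noise_sd_mM: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd_mM < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.sample_times_h[0] != 0:
            raise ValueError("sampling must start at 0 h")
        lo, hi = self.tissue_mass_range_g
        if not 0 < lo <= hi:
            raise ValueError("bad tissue mass range")


@dataclass(frozen=True)
class GroundTruth:
    """True per-condition rates (nmol/million cells/h) and animal effects.

    ``rates`` maps (region, treatment) -> (gcr, lpr). ``animal_effect_sd``
    is the SD of a per-animal additive offset applied to both rates.
    The glycolytic stoichiometry caps lactate at two per glucose.
    """

    rates: dict
    animal_effect_sd: float = 0.0
    stoichiometry_slack: float = 1e-9

    def __post_init__(self):
        for (region, treatment), (gcr, lpr) in self.rates.items():
            if gcr < 0 or lpr < 0:
                raise ValueError("true rates must be nonnegative")
            if lpr > 2.0 * gcr + self.stoichiometry_slack:
                raise ValueError(
                    f"({region}, {treatment}): LPR {lpr} exceeds the "
                    f"glycolytic ceiling of 2 x GCR = {2 * gcr}"
                )


def default_ground_truth(animal_effect_sd: float = 0.0) -> GroundTruth:
    """Plausible true rates centred on measured rat-disc condition means."""
    rates = {
        ("NP", "control"): (149.13, 195.30),
        ("AF", "control"): (80.57, 94.89),
        ("CEP", "control"): (40.23, 54.65),
        ("NP", "cse"): (81.74, 114.47),
        ("AF", "cse"): (49.16, 71.09),
        ("CEP", "cse"): (26.60, 40.03),
        ("NP", "low_nutrient"): (52.13, 92.97),
        ("AF", "low_nutrient"): (24.07, 38.51),
        ("CEP", "low_nutrient"): (18.27, 26.77),
    }
    return GroundTruth(rates=rates, animal_effect_sd=animal_effect_sd)


def generate_cohort(design: AssayDesign, truth: GroundTruth | None = None):
    """Generate a cohort of CultureWells plus a ground-truth record.

    Per well: tissue mass is drawn uniformly from the design range, the
    buoyant weight is back-computed from an assumed tissue density, the
    cell count follows from regional cell density, and concentration
    trajectories are integrated under constant true rates before noise is
    added to every reading. Deterministic under the design seed.

    Raises ``ValueError`` if any noiseless trajectory would drive media
    glucose below the 0.5 mM viability floor within the sampling period.
    """
    truth = truth or default_ground_truth()
    rng = np.random.default_rng(design.seed)
    t = np.asarray(design.sample_times_h, dtype=float)

    animal_ids = [f"A{i + 1:02d}" for i in range(design.n_animals)]
    offsets = {
        a: (rng.normal(0.0, truth.animal_effect_sd) if truth.animal_effect_sd else 0.0)
        for a in animal_ids
    }

    wells, records = [], []
    for animal in animal_ids:
        for region in design.regions:
            for treatment, cond in design.treatments.items():
                if (region, treatment) not in truth.rates:
                    raise ValueError(f"no ground truth for ({region}, {treatment})")
                base_gcr, base_lpr = truth.rates[(region, treatment)]
                gcr = max(base_gcr + offsets[animal], 0.0)
                lpr = max(base_lpr + offsets[animal], 0.0)
                for rep in range(design.replicates):
                    mass = rng.uniform(*design.tissue_mass_range_g)
                    v_tissue = mass / TISSUE_DENSITY  # cm^3
                    buoyant = mass - RHO_PBS * v_tissue
                    cells = DEFAULT_CELL_DENSITY[region] * v_tissue  # Mcells
                    v_media = design.media_volume_ml[region]

                    # mM change per hour from a rate in nmol/Mcells/h
                    slope_g = gcr * cells / (1000.0 * v_media)
                    slope_l = lpr * cells / (1000.0 * v_media)
                    glu = cond.glucose_mM - slope_g * t
                    lac = slope_l * t  # media starts lactate-free
                    if glu.min() < GLUCOSE_VIABILITY_FLOOR_MM:
                        raise ValueError(
                            f"design refused: ({region}, {treatment}) at "
                            f"{mass * 1000:.0f} mg would draw glucose to "
                            f"{glu.min():.2f} mM, below the "
                            f"{GLUCOSE_VIABILITY_FLOOR_MM} mM viability floor"
                        )
                    if design.noise_sd_mM > 0:
                        glu = glu + rng.normal(0, design.noise_sd_mM, size=t.shape)
                        lac = lac + rng.normal(0, design.noise_sd_mM, size=t.shape)
                    glu = np.clip(glu, 0.0, None)
                    lac = np.clip(lac, 0.0, None)

                    well_id = f"{animal}-{region}-{treatment}-r{rep + 1}"
                    wells.append(
                        CultureWell(
                            animal_id=animal,
                            region=region,
                            treatment=treatment,
                            wet_weight=mass,
                            buoyant_weight=buoyant,
                            media_volume=v_media,
                            times=tuple(t),
                            glucose_series=tuple(glu),
                            lactate_series=tuple(lac),
                            well_id=well_id,
                        )
                    )
                    records.append(
                        {
                            "well_id": well_id,
                            "animal_id": animal,
                            "region": region,
                            "treatment": treatment,
                            "true_gcr": gcr,
                            "true_lpr": lpr,
                            "animal_offset": offsets[animal],
                            "tissue_mass_g": mass,
                            "cells_Mcells": cells,
                        }
                    )
    return wells, pd.DataFrame(records)


def cohort_to_frames(wells: Sequence[CultureWell]):
    """Emit the two long-format tables the assay module consumes."""
    meas, meta = [], []
    for w in wells:
        meta.append(
            {
                "well_id": w.well_id,
                "animal_id": w.animal_id,
                "region": w.region,
                "treatment": w.treatment,
                "wet_weight_g": w.wet_weight,
                "buoyant_weight_g": w.buoyant_weight,
                "media_volume_mL": w.media_volume,
            }
        )
        for t, g, l in zip(w.times, w.glucose_series, w.lactate_series):
            meas.append(
                {"well_id": w.well_id, "time_h": t, "glucose_mM": g, "lactate_mM": l}
            )
    return pd.DataFrame(meas), pd.DataFrame(meta)


def generate_mm_dataset(
    true_params: MMPair,
    concs: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Saturation-curve dataset: rates at the given concentrations + noise."""
    c = np.asarray(concs, dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    rng = np.random.default_rng(seed)
    rates = true_params.vmax * c / (true_params.km + c)
    if noise_sd > 0:
        rates = rates + rng.normal(0, noise_sd, size=c.shape)
    return c, np.clip(rates, 0.0, None)
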