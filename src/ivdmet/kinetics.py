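"""Metabolic rate laws for disc cells.

Glucose consumption and lactate production follow Michaelis-Menten kinetics
in the local glucose concentration; the saturating rate (Vmax) and
half-saturation constant (Km) depend on region, dissolved-oxygen level and
cigarette-smoke-extract (CSE) exposure. Oxygen consumption and ATP synthesis
are coupled to the glucose/lactate rates through the stoichiometry of
glycolysis and oxidative phosphorylation:

    Q_oxygen = 3 Q_lactate + 6 Q_glucose   (0 when lactate outruns 2x glucose)
    Q_ATP    = -2 Q_glucose - 6 Q_oxygen

so pure glycolysis yields two ATP per glucose and full oxidation up to 38.

Parameter sets are anchored at 1% and 5% oxygen and interpolated linearly in
dissolved-oxygen concentration between the anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import curve_fit

from .units import RATE_TO_MM_PER_S

__all__ = [
    "MMPair",
    "MMFit",
    "RegionKinetics",
    "EffectiveParams",
    "VolumetricRates",
    "fit_michaelis_menten",
    "interpolate_params",
    "reaction_rates",
    "load_reference_kinetics",
]

REGIONS = ("NP", "AF", "CEP")

#: Upper bound for Km during fitting (mM); fits pinned here are flagged.
KM_UPPER_BOUND = 1.0e3

#: Floor applied to extrapolated kinetic parameters (Vmax and Km).
PARAM_FLOOR = 1.0e-9

#: Oxygen-availability regularisation scale (mM): Q_oxygen is multiplied by
#: c_o2 / (c_o2 + EPS_O2) so the sink vanishes smoothly as oxygen does.
#: Negligible above a few uM.
EPS_O2 = 1.0e-4


@dataclass(frozen=True)
class MMPair:
    """A (Vmax, Km) pair: Vmax in nmol/million cells/h, Km in mM."""

    vmax: float
    km: float

    def __post_init__(self):
        if self.vmax < 0:
            raise ValueError(f"Vmax must be nonnegative, got {self.vmax}")
        if not np.isnan(self.km) and self.km <= 0:
            raise ValueError(f"Km must be positive, got {self.km}")

    def rate(self, c):
        """Saturating rate at substrate concentration c (mM)."""
        return self.vmax * np.asarray(c, dtype=float) / (self.km + c)


@dataclass(frozen=True)
class MMFit:
    """Result of a Michaelis-Menten least-squares fit."""

    pair: MMPair
    residual_norm: float
    km_indeterminate: bool = False
    km_at_bound: bool = False

    @property
    def vmax(self) -> float:
        return self.pair.vmax

    @property
    def km(self) -> float:
        return self.pair.km


@dataclass(frozen=True)
class RegionKinetics:
    """Kinetic and transport parameters for one region at one oxygen anchor.

    Diffusivities are in m^2/s as tabulated; cell_density in million cells
    per mL of tissue. The CSE pairs share Km with the untreated pairs —
    smoke exposure rescales the saturating rates only.
    """

    region: str
    o2_level: float  # anchor dissolved-oxygen concentration, mM
    glucose_mm: MMPair
    glucose_mm_cse: MMPair
    lactate_mm: MMPair
    lactate_mm_cse: MMPair
    cell_density: float
    d_glucose: float
    d_lactate: float
    d_oxygen: float

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        for name in ("cell_density", "d_glucose", "d_lactate", "d_oxygen"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EffectiveParams:
    """Oxygen-interpolated MM parameters; each field is scalar or ndarray."""

    vmax_glucose: np.ndarray
    km_glucose: np.ndarray
    vmax_lactate: np.ndarray
    km_lactate: np.ndarray


@dataclass(frozen=True)
class VolumetricRates:
    """Volumetric reaction rates (mM/s); each field is scalar or ndarray.

    Sign convention: consumption negative, production positive.
    """

    q_glucose: np.ndarray
    q_lactate: np.ndarray
    q_oxygen: np.ndarray
    q_atp: np.ndarray


def _mm_model(c, vmax, km):
    return vmax * c / (km + c)


def fit_michaelis_menten(concs, rates) -> MMFit:
    """Least-squares fit of rate = Vmax c / (Km + c).

    Parameters
    ----------
    concs : array-like of mM, at least two distinct values.
    rates : array-like of nmol/million cells/h, nonnegative.

    Notes
    -----
    With all-zero rates the model degenerates: Vmax = 0 is returned and Km is
    reported indeterminate (NaN). Data that stay in the linear (c << Km)
    regime drive Km to its upper bound; the fit is returned but flagged.
    """
    c = np.asarray(concs, dtype=float)
    r = np.asarray(rates, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise ValueError("concs and rates must be 1-D and of equal length")
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct concentrations to fit")
    if np.any(r < 0) or np.any(c < 0):
        raise ValueError("concentrations and rates must be nonnegative")

    if np.all(r == 0):
        return MMFit(MMPair(0.0, float("nan")), 0.0, km_indeterminate=True)

    p0 = (float(r.max()), float(np.median(c)))
    try:
        popt, _ = curve_fit(
            _mm_model, c, r, p0=p0,
            bounds=([0.0, 1e-9], [np.inf, KM_UPPER_BOUND]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    resid = float(np.linalg.norm(r - _mm_model(c, vmax, km)))
    # Km far above the sampled range means the data never left the linear
    # regime and only the ratio Vmax/Km is identified.
    at_bound = km > 0.99 * KM_UPPER_BOUND or km > 20.0 * float(c.max())
    return MMFit(MMPair(vmax, km), resid, km_at_bound=at_bound)


def interpolate_params(
    c_o2,
    p_low: RegionKinetics,
    p_high: RegionKinetics,
    cse: bool = False,
    mode: str = "vmax_to_origin",
) -> EffectiveParams:
    """Interpolate MM parameters linearly in dissolved-oxygen concentration.

    Between the anchors (by default 0.011 mM at 1% and 0.054 mM at 5%) each
    of Vmax_glucose, Km_glucose, Vmax_lactate, Km_lactate varies linearly in
    c_o2. Above the upper anchor parameters clamp to the 5% set. Below the
    lower anchor, ``mode`` selects:

    - ``vmax_to_origin`` (default): the Vmax interpolation table is extended
      through the origin, so below the 1% anchor every Vmax scales as
      c_o2 / c(1%) while Km holds its 1% value. The oxygen sink then
      vanishes linearly with oxygen, which guarantees a strictly positive
      steady-state oxygen field with no extra regularisation;
    - ``glycolytic``: Vmax continues the anchor line toward c_o2 = 0 while
      Km holds its 1% value, driving the lactate:glucose rate ratio toward
      the glycolytic ceiling of 2 as oxygen vanishes;
    - ``extrapolate_to_zero``: continue the anchor line toward c_o2 = 0 for
      all four parameters, flooring each at a small positive epsilon (a
      residual oxygen sink then persists to c_o2 = 0 and only the
      availability regularisation keeps the field nonnegative);
    - ``clamp``: hold the 1% set.

    Negative c_o2 is clamped to zero with a warning (the nonlinear solver
    must never raise mid-iteration).
    """
    if mode not in ("vmax_to_origin", "glycolytic", "extrapolate_to_zero", "clamp"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    if p_low.o2_level >= p_high.o2_level:
        raise ValueError("p_low must be anchored below p_high")
    c = np.asarray(c_o2, dtype=float)
    if np.any(np.isnan(c)):
        raise ValueError("c_o2 contains NaN")
    if np.any(c < 0):
        warnings.warn("negative oxygen concentration clamped to 0", RuntimeWarning)
        c = np.clip(c, 0.0, None)

    lo, hi = p_low.o2_level, p_high.o2_level
    frac = (c - lo) / (hi - lo)
    frac = np.minimum(frac, 1.0)  # clamp above the 5% anchor
    frac_clamped = np.maximum(frac, 0.0)
    if mode == "clamp":
        frac_vmax = frac_km = frac_clamped
    elif mode == "extrapolate_to_zero":
        frac_vmax = frac_km = frac
    else:  # glycolytic / vmax_to_origin: Km holds its 1% value below anchor
        frac_vmax, frac_km = frac, frac_clamped
    # Below-anchor Vmax scale for the through-origin table: c / c(1%).
    sub_scale = np.clip(c / lo, 0.0, 1.0)

    def pick(rk: RegionKinetics, which: str) -> MMPair:
        if which == "glucose":
            return rk.glucose_mm_cse if cse else rk.glucose_mm
        return rk.lactate_mm_cse if cse else rk.lactate_mm

    def lerp(a, b, f):
        return np.maximum(a + (b - a) * f, PARAM_FLOOR)

    def lerp_vmax(a, b):
        # Vmax may legitimately reach zero; only Km needs a positive floor.
        if mode == "vmax_to_origin":
            v = np.maximum(a + (b - a) * np.maximum(frac_vmax, 0.0), 0.0)
            return v * sub_scale
        return np.maximum(a + (b - a) * frac_vmax, 0.0)

    g_lo, g_hi = pick(p_low, "glucose"), pick(p_high, "glucose")
    l_lo, l_hi = pick(p_low, "lactate"), pick(p_high, "lactate")
    return EffectiveParams(
        vmax_glucose=lerp_vmax(g_lo.vmax, g_hi.vmax),
        km_glucose=lerp(g_lo.km, g_hi.km, frac_km),
        vmax_lactate=lerp_vmax(l_lo.vmax, l_hi.vmax),
        km_lactate=lerp(l_lo.km, l_hi.km, frac_km),
    )


def reaction_rates(
    c_glu,
    c_o2,
    rk_pair,
    cse: bool = False,
    mode: str = "vmax_to_origin",
    eps_o2: float = EPS_O2,
) -> VolumetricRates:
    """Volumetric glucose/lactate/oxygen/ATP rates (mM/s) at local state.

    Parameters
    ----------
    c_glu, c_o2 : scalar or ndarray local concentrations (mM).
    rk_pair : (RegionKinetics at 1%, RegionKinetics at 5%).
    cse : use the CSE Vmax set.
    eps_o2 : oxygen-availability regularisation scale (mM); the oxygen sink
        is scaled by c_o2/(c_o2 + eps_o2) so it vanishes with oxygen.

    Both glucose consumption and lactate production are driven by the local
    glucose concentration; oxygen enters through the parameter interpolation
    and the stoichiometric coupling only.
    """
    p_low, p_high = rk_pair
    cg = np.asarray(c_glu, dtype=float)
    co = np.asarray(c_o2, dtype=float)
    if np.any(np.isnan(cg)) or np.any(np.isnan(co)):
        raise ValueError("NaN concentration input")
    cg = np.clip(cg, 0.0, None)
    eff = interpolate_params(co, p_low, p_high, cse=cse, mode=mode)
    co = np.clip(co, 0.0, None)

    rho = p_low.cell_density
    q_glu = -rho * eff.vmax_glucose * cg / (eff.km_glucose + cg) / RATE_TO_MM_PER_S
    q_lac = rho * eff.vmax_lactate * cg / (eff.km_lactate + cg) / RATE_TO_MM_PER_S
    q_o2_raw = 3.0 * q_lac + 6.0 * q_glu
    # Glycolytic branch: no oxygen consumed when lactate outruns 2x glucose.
    q_o2_raw = np.where(q_lac > -2.0 * q_glu, 0.0, q_o2_raw)
    q_o2 = q_o2_raw * co / (co + eps_o2)
    q_atp = -2.0 * q_glu - 6.0 * q_o2
    if np.isscalar(c_glu) and np.isscalar(c_o2):
        return VolumetricRates(float(q_glu), float(q_lac), float(q_o2), float(q_atp))
    return VolumetricRates(q_glu, q_lac, q_o2, q_atp)


def _pair(block: dict, rate: str, cse: bool) -> MMPair:
    key = "cse" if cse else "nocse"
    return MMPair(block[f"vmax_{rate}_{key}"], block[f"km_{rate}"])


def load_reference_kinetics(path=None) -> dict:
    """Load the packaged per-region kinetic/transport parameter sets.

    Returns ``{region: (RegionKinetics at 1% O2, RegionKinetics at 5% O2)}``.
    A different YAML file with the same layout may be supplied via ``path``.
    """
    if path is None:
        text = resources.files("ivdmet").joinpath("data/rat_disc_kinetics.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = {}
    for region, blk in raw["regions"].items():
        levels = sorted(blk["levels"], key=lambda d: d["o2_conc_mM"])
        if len(levels) != 2:
            raise ValueError(f"region {region}: expected 2 oxygen levels")
        pair = tuple(
            RegionKinetics(
                region=region,
                o2_level=float(lev["o2_conc_mM"]),
                glucose_mm=_pair(lev, "gcr", False),
                glucose_mm_cse=_pair(lev, "gcr", True),
                lactate_mm=_pair(lev, "lpr", False),
                lactate_mm_cse=_pair(lev, "lpr", True),
                cell_density=float(blk["cell_density"]),
                d_glucose=float(blk["d_glucose"]),
                d_lactate=float(blk["d_lactate"]),
                d_oxygen=float(blk["d_oxygen"]),
            )
            for lev in levels
        )
        out[region] = pair
    missing = set(REGIONS) - set(out)
    if missing:
        raise ValueError(f"parameter file missing regions: {sorted(missing)}")
    return out
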