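"""Steady-state nutrient transport in an idealised cylindrical disc.

The disc is a cylinder (radius 1.5 mm, height 1 mm) partitioned into a
nucleus pulposus (NP) core (radius 0.85 mm), an annulus fibrosus (AF) ring,
and cartilaginous endplate (CEP) slabs of 0.2 mm spanning the full radius at
the top and bottom faces. All external surfaces see fixed culture-media
concentrations (Dirichlet); the axis r = 0 is a symmetry line.

For each solute i, steady diffusion with a metabolic source obeys

    -div(D_i grad c_i) = Q_i

discretised by a cell-centred finite-volume scheme on a uniform (r, z) grid
in cylindrical coordinates (the geometry, boundary data and kinetics are all
axisymmetric). Interface diffusivities use harmonic means so flux is
continuous across region boundaries. The glucose-oxygen coupling is resolved
by damped Picard iteration with the local sinks linearised implicitly
(coefficient from the previous iterate times the new concentration), which
preserves the M-matrix property and hence positivity and the maximum
principle at every iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .kinetics import EPS_O2, RATE_TO_MM_PER_S, interpolate_params
from .units import M2_TO_MM2, O2_CONC_1PCT_MM, O2_CONC_5PCT_MM

__all__ = [
    "DiscGeometry",
    "AxiGrid",
    "Scenario",
    "FieldSolution",
    "ConvergenceError",
    "classify_region",
    "build_grid",
    "linear_diffusion_solve",
    "solve_steady_state",
    "PRESET_SCENARIOS",
]

REGION_CODES = {"NP": 0, "AF": 1, "CEP": 2}
CODE_REGIONS = {v: k for k, v in REGION_CODES.items()}


class ConvergenceError(RuntimeError):
    """Nonlinear iteration failed; carries the last iterate and history."""

    def __init__(self, msg, last_solution=None, residual_history=None):
        super().__init__(msg)
        self.last_solution = last_solution
        self.residual_history = residual_history or []


@dataclass(frozen=True)
class DiscGeometry:
    """Idealised rat lumbar disc geometry (mm)."""

    radius: float = 1.5
    height: float = 1.0
    np_radius: float = 0.85
    cep_thickness: float = 0.2

    def __post_init__(self):
        if not 0 < self.np_radius < self.radius:
            raise ValueError("require 0 < np_radius < radius")
        if not 0 < 2 * self.cep_thickness < self.height:
            raise ValueError("require 2*cep_thickness < height")

    def region_volumes(self) -> dict:
        """Closed-form region volumes (mm^3) under the full-radius CEP rule."""
        core_h = self.height - 2 * self.cep_thickness
        v_cep = np.pi * self.radius**2 * 2 * self.cep_thickness
        v_np = np.pi * self.np_radius**2 * core_h
        v_af = np.pi * (self.radius**2 - self.np_radius**2) * core_h
        return {"CEP": v_cep, "NP": v_np, "AF": v_af}

    def total_volume(self) -> float:
        return np.pi * self.radius**2 * self.height


def classify_region(r: float, z: float, geom: DiscGeometry) -> str:
    """Region label at point (r, z) mm.

    CEP occupies the full-radius slabs within cep_thickness of either face;
    between them the NP core (r < np_radius) is wrapped by the AF ring.
    """
    if not (0 <= r <= geom.radius) or not (0 <= z <= geom.height):
        raise ValueError(f"point (r={r}, z={z}) outside the disc domain")
    if z < geom.cep_thickness or z > geom.height - geom.cep_thickness:
        return "CEP"
    return "NP" if r < geom.np_radius else "AF"


@dataclass(frozen=True)
class AxiGrid:
    """Uniform cell-centred axisymmetric grid.

    Arrays are shaped (nr, nz): first index radial, second axial.
    """

    geom: DiscGeometry
    nr: int
    nz: int
    dr: float
    dz: float
    r: np.ndarray  # (nr,) cell-centre radii
    z: np.ndarray  # (nz,) cell-centre heights
    region_codes: np.ndarray  # (nr, nz) int
    cell_volumes: np.ndarray = field(repr=False, default=None)  # (nr, nz) mm^3

    @property
    def shape(self):
        return (self.nr, self.nz)

    @property
    def n_cells(self):
        return self.nr * self.nz

    def region_labels(self) -> np.ndarray:
        return np.vectorize(CODE_REGIONS.get)(self.region_codes)

    def region_mask(self, region: str) -> np.ndarray:
        return self.region_codes == REGION_CODES[region]


def build_grid(geom: DiscGeometry, nr: int, nz: int) -> AxiGrid:
    """Build the uniform grid and label cells by region at their centres."""
    if nr < 8 or nz < 8:
        raise ValueError("need nr, nz >= 8")
    dr = geom.radius / nr
    dz = geom.height / nz
    if dr > geom.np_radius / 4:
        raise ValueError(
            f"nr={nr} too coarse: need dr <= np_radius/4, i.e. "
            f"nr >= {int(np.ceil(4 * geom.radius / geom.np_radius))}"
        )
    if dz > geom.cep_thickness / 4:
        raise ValueError(
            f"nz={nz} too coarse: need dz <= cep_thickness/4, i.e. "
            f"nz >= {int(np.ceil(4 * geom.height / geom.cep_thickness))}"
        )
    r = (np.arange(nr) + 0.5) * dr
    z = (np.arange(nz) + 0.5) * dz
    rr, zz = np.meshgrid(r, z, indexing="ij")
    codes = np.empty((nr, nz), dtype=np.int8)
    cep = (zz < geom.cep_thickness) | (zz > geom.height - geom.cep_thickness)
    np_core = ~cep & (rr < geom.np_radius)
    codes[...] = REGION_CODES["AF"]
    codes[np_core] = REGION_CODES["NP"]
    codes[cep] = REGION_CODES["CEP"]
    vol = 2 * np.pi * rr * dr * dz
    return AxiGrid(geom, nr, nz, dr, dz, r, z, codes, vol)


@dataclass(frozen=True)
class Scenario:
    """One model run: boundary concentrations (mM) and the CSE flag."""

    name: str
    c0_glucose: float
    c0_oxygen: float
    c0_lactate: float
    cse: bool = False

    def __post_init__(self):
        if min(self.c0_glucose, self.c0_oxygen, self.c0_lactate) < 0:
            raise ValueError("boundary concentrations must be nonnegative")


#: The four study conditions. Physiological media: 5.5 mM glucose, 5% oxygen
#: (0.054 mM dissolved), 0.9 mM lactate; low-nutrient media: 1.5 mM glucose,
#: 1% oxygen (0.011 mM). CSE acts through the smoke-exposed Vmax set.
PRESET_SCENARIOS = {
    "physiological": Scenario("physiological", 5.5, O2_CONC_5PCT_MM, 0.9, False),
    "cse": Scenario("cse", 5.5, O2_CONC_5PCT_MM, 0.9, True),
    "low_nutrient": Scenario("low_nutrient", 1.5, O2_CONC_1PCT_MM, 0.9, False),
    "cse_low_nutrient": Scenario("cse_low_nutrient", 1.5, O2_CONC_1PCT_MM, 0.9, True),
}


@dataclass
class FieldSolution:
    """Converged steady-state fields on the grid (mM; q_atp in mM/s)."""

    scenario: Scenario
    glucose: np.ndarray
    lactate: np.ndarray
    oxygen: np.ndarray
    q_atp: np.ndarray
    residual: float
    iterations: int
    converged: bool = True


# ---------------------------------------------------------------------------
# Linear finite-volume solve


def _operator(grid: AxiGrid, D: np.ndarray, sink: np.ndarray | None):
    """Assemble A and the boundary-conductance vector for -div(D grad c).

    A c = q*V + G_b * c0, with A an M-matrix. D in mm^2/s, shaped (nr, nz).
    Returns (A in CSR, boundary conductance per cell flattened).
    """
    nr, nz = grid.shape
    dr, dz = grid.dr, grid.dz
    r = grid.r
    n = grid.n_cells
    idx = np.arange(n).reshape(nr, nz)

    diag = np.zeros((nr, nz))
    rows, cols, vals = [], [], []
    gb = np.zeros((nr, nz))

    # Radial internal faces between (i, :) and (i+1, :)
    r_face = (np.arange(1, nr) * dr)[:, None]  # (nr-1, 1)
    d_face = 2.0 * D[:-1, :] * D[1:, :] / (D[:-1, :] + D[1:, :])
    g = d_face * (2 * np.pi * r_face * dz) / dr  # (nr-1, nz)
    diag[:-1, :] += g
    diag[1:, :] += g
    rows.append(idx[:-1, :].ravel()); cols.append(idx[1:, :].ravel()); vals.append(-g.ravel())
    rows.append(idx[1:, :].ravel()); cols.append(idx[:-1, :].ravel()); vals.append(-g.ravel())

    # Axial internal faces between (:, j) and (:, j+1)
    d_face = 2.0 * D[:, :-1] * D[:, 1:] / (D[:, :-1] + D[:, 1:])
    g = d_face * (2 * np.pi * r[:, None] * dr) / dz  # (nr, nz-1)
    diag[:, :-1] += g
    diag[:, 1:] += g
    rows.append(idx[:, :-1].ravel()); cols.append(idx[:, 1:].ravel()); vals.append(-g.ravel())
    rows.append(idx[:, 1:].ravel()); cols.append(idx[:, :-1].ravel()); vals.append(-g.ravel())

    # Dirichlet boundaries: outer radius, z = 0 and z = H faces
    # (half-cell distance, cell's own D). The axis r = 0 face has zero area.
    g_out = D[-1, :] * (2 * np.pi * grid.geom.radius * dz) / (dr / 2)
    gb[-1, :] += g_out
    g_bot = D[:, 0] * (2 * np.pi * r * dr) / (dz / 2)
    gb[:, 0] += g_bot
    g_top = D[:, -1] * (2 * np.pi * r * dr) / (dz / 2)
    gb[:, -1] += g_top
    diag += gb

    if sink is not None:
        diag = diag + sink * grid.cell_volumes

    rows.append(idx.ravel()); cols.append(idx.ravel()); vals.append(diag.ravel())
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A, gb.ravel()


def linear_diffusion_solve(
    grid: AxiGrid,
    diffusivity: np.ndarray,
    source: np.ndarray,
    boundary_value: float,
    sink: np.ndarray | None = None,
) -> np.ndarray:
    """Solve -div(D grad c) = source - sink*c with Dirichlet boundaries.

    Parameters
    ----------
    diffusivity : (nr, nz) mm^2/s, positive.
    source : (nr, nz) mM/s (explicit part of Q).
    boundary_value : fixed concentration (mM) on all external surfaces.
    sink : optional (nr, nz) nonnegative linear sink coefficient (1/s).

    The symmetry axis carries zero flux (its face area vanishes). Discrete
    flux conservation holds: total reaction = net boundary inflow.
    """
    D = np.broadcast_to(np.asarray(diffusivity, dtype=float), grid.shape)
    if np.any(D <= 0):
        raise ValueError("diffusivities must be positive")
    if boundary_value < 0:
        raise ValueError("Dirichlet value must be nonnegative")
    q = np.broadcast_to(np.asarray(source, dtype=float), grid.shape)
    A, gb = _operator(grid, D, sink)
    b = q.ravel() * grid.cell_volumes.ravel() + gb * boundary_value
    c = splu(A.tocsc()).solve(b)
    return c.reshape(grid.shape)


def boundary_flux(grid: AxiGrid, diffusivity, field: np.ndarray, boundary_value: float) -> float:
    """Net diffusive inflow (mm^3 * mM / s) across the Dirichlet boundary."""
    D = np.broadcast_to(np.asarray(diffusivity, dtype=float), grid.shape)
    _, gb = _operator(grid, D, None)
    return float(np.sum(gb * (boundary_value - field.ravel())))


# ---------------------------------------------------------------------------
# Nonlinear coupled solve


def _per_cell_parameters(grid: AxiGrid, params: dict):
    """Expand the region parameter dict to per-cell arrays."""
    shape = grid.shape
    out = {
        "rho": np.empty(shape),
        "d_glu": np.empty(shape),
        "d_lac": np.empty(shape),
        "d_o2": np.empty(shape),
    }
    for region, (lo, hi) in params.items():
        m = grid.region_mask(region)
        out["rho"][m] = lo.cell_density
        out["d_glu"][m] = lo.d_glucose * M2_TO_MM2
        out["d_lac"][m] = lo.d_lactate * M2_TO_MM2
        out["d_o2"][m] = lo.d_oxygen * M2_TO_MM2
    return out


def _effective_params(grid: AxiGrid, params: dict, c_o2: np.ndarray, cse: bool, mode: str):
    """Per-cell oxygen-interpolated (Vmax, Km) arrays for both rates."""
    vg = np.empty(grid.shape); kg = np.empty(grid.shape)
    vl = np.empty(grid.shape); kl = np.empty(grid.shape)
    for region, (lo, hi) in params.items():
        m = grid.region_mask(region)
        eff = interpolate_params(c_o2[m], lo, hi, cse=cse, mode=mode)
        vg[m] = eff.vmax_glucose; kg[m] = eff.km_glucose
        vl[m] = eff.vmax_lactate; kl[m] = eff.km_lactate
    return vg, kg, vl, kl


def solve_steady_state(
    grid: AxiGrid,
    scenario: Scenario,
    params: dict,
    tol: float = 1e-8,
    max_iter: int = 500,
    damping: float = 0.5,
    o2_mode: str = "vmax_to_origin",
    eps_o2: float = EPS_O2,
) -> FieldSolution:
    """Solve the coupled steady-state glucose-oxygen-lactate system.

    Damped Picard iteration: at each outer step the kinetic parameters are
    interpolated at the current oxygen field, the glucose and oxygen sinks
    are linearised about the current iterate, and the two linear diffusion
    problems are re-solved; iterates are under-relaxed by ``damping``.
    Lactate (a pure source problem) and the ATP synthesis field are computed
    once from the converged glucose/oxygen fields.

    Convergence is measured as the max field change relative to the boundary
    concentration of each coupled solute.
    """
    if not params or set(params) != {"NP", "AF", "CEP"}:
        raise ValueError("params must map exactly the regions NP, AF, CEP")
    per_cell = _per_cell_parameters(grid, params)
    rho = per_cell["rho"]

    cg = np.full(grid.shape, scenario.c0_glucose)
    co = np.full(grid.shape, scenario.c0_oxygen)
    history = []
    glu_scale = max(scenario.c0_glucose, 1e-12)
    o2_scale = max(scenario.c0_oxygen, 1e-12)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        vg, kg, vl, kl = _effective_params(grid, params, co, scenario.cse, o2_mode)

        # Glucose: Q = -rho Vmax c/(Km + c); implicit as sink k_g * c with
        # k_g = rho Vmax / (Km + c_prev) (1/s).
        k_glu = rho * vg / (kg + cg) / RATE_TO_MM_PER_S
        cg_new = linear_diffusion_solve(
            grid, per_cell["d_glu"], 0.0, scenario.c0_glucose, sink=k_glu
        )

        # Oxygen sink from the stoichiometric coupling at the current state,
        # regularised by oxygen availability: k_o2 = |Q_o2| / (c_prev + eps).
        q_glu = -rho * vg * cg / (kg + cg) / RATE_TO_MM_PER_S
        q_lac = rho * vl * cg / (kl + cg) / RATE_TO_MM_PER_S
        q_o2 = 3.0 * q_lac + 6.0 * q_glu
        q_o2 = np.where(q_lac > -2.0 * q_glu, 0.0, q_o2)
        k_o2 = -q_o2 / (co + eps_o2)
        co_new = linear_diffusion_solve(
            grid, per_cell["d_o2"], 0.0, scenario.c0_oxygen, sink=k_o2
        )

        cg_next = (1 - damping) * cg + damping * cg_new
        co_next = (1 - damping) * co + damping * co_new
        resid = max(
            float(np.abs(cg_next - cg).max()) / glu_scale,
            float(np.abs(co_next - co).max()) / o2_scale,
        )
        history.append(resid)
        cg, co = cg_next, co_next
        if resid < tol:
            converged = True
            break

    assert cg.min() > -1e-12 and co.min() > -1e-12, "negative concentration"
    cg = np.clip(cg, 0.0, None)
    co = np.clip(co, 0.0, None)

    # Final rates at the converged state.
    vg, kg, vl, kl = _effective_params(grid, params, co, scenario.cse, o2_mode)
    q_glu = -rho * vg * cg / (kg + cg) / RATE_TO_MM_PER_S
    q_lac = rho * vl * cg / (kl + cg) / RATE_TO_MM_PER_S
    q_o2 = 3.0 * q_lac + 6.0 * q_glu
    q_o2 = np.where(q_lac > -2.0 * q_glu, 0.0, q_o2)
    q_o2 = q_o2 * co / (co + eps_o2)
    q_atp = -2.0 * q_glu - 6.0 * q_o2

    c_lac = linear_diffusion_solve(
        grid, per_cell["d_lac"], q_lac, scenario.c0_lactate
    )

    sol = FieldSolution(
        scenario=scenario,
        glucose=cg,
        lactate=c_lac,
        oxygen=co,
        q_atp=q_atp,
        residual=history[-1] if history else 0.0,
        iterations=it,
        converged=converged,
    )
    if not converged:
        raise ConvergenceError(
            f"Picard iteration did not reach tol={tol} in {max_iter} steps "
            f"(last residual {sol.residual:.3e})",
            last_solution=sol,
            residual_history=history,
        )
    return sol
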