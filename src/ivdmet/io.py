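"""Field export: long-format CSV and legacy-ASCII VTK structured grids."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .transport import AxiGrid, FieldSolution

__all__ = ["fields_to_frame", "write_fields_csv", "write_vtk"]


def fields_to_frame(solution: FieldSolution, grid: AxiGrid) -> pd.DataFrame:
    """One row per cell: (r, z, region, fields). q_atp in uM/s."""
    rr, zz = np.meshgrid(grid.r, grid.z, indexing="ij")
    return pd.DataFrame(
        {
            "r_mm": rr.ravel(),
            "z_mm": zz.ravel(),
            "region": grid.region_labels().ravel(),
            "glucose_mM": solution.glucose.ravel(),
            "lactate_mM": solution.lactate.ravel(),
            "oxygen_mM": solution.oxygen.ravel(),
            "qatp_uM_per_s": solution.q_atp.ravel() * 1e3,
        }
    )


def write_fields_csv(solution: FieldSolution, grid: AxiGrid, path) -> None:
    fields_to_frame(solution, grid).to_csv(path, index=False)


def write_vtk(solution: FieldSolution, grid: AxiGrid, path) -> None:
    """Write cell-centre fields as a legacy-ASCII VTK structured grid.

    The axisymmetric (r, z) plane is exported as a flat nr x nz x 1 sheet
    with one scalar array per solute plus the ATP synthesis rate.
    """
    nr, nz = grid.shape
    arrays = {
        "glucose_mM": solution.glucose,
        "lactate_mM": solution.lactate,
        "oxygen_mM": solution.oxygen,
        "qatp_uM_per_s": solution.q_atp * 1e3,
    }
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"ivdmet fields: scenario {solution.scenario.name}\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nr} {nz} 1\n")
        fh.write(f"POINTS {nr * nz} double\n")
        for iz in range(nz):
            for ir in range(nr):
                fh.write(f"{grid.r[ir]:.8g} {grid.z[iz]:.8g} 0\n")
        fh.write(f"POINT_DATA {nr * nz}\n")
        for name, arr in arrays.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for iz in range(nz):
                for ir in range(nr):
                    fh.write(f"{arr[ir, iz]:.10g}\n")
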