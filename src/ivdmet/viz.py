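"""Convenience plots: field contours and regional availability bars."""

from __future__ import annotations

import numpy as np

from .transport import AxiGrid, FieldSolution

__all__ = ["plot_fields"]

_PANELS = [
    ("q_atp", "ATP synthesis (uM/s)", 1e3),
    ("glucose", "Glucose (mM)", 1.0),
    ("lactate", "Lactate (mM)", 1.0),
    ("oxygen", "Oxygen (mM)", 1.0),
]


def plot_fields(solution: FieldSolution, grid: AxiGrid):
    """2x2 pseudocolour maps of the (r, z) half-plane fields."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 6), constrained_layout=True)
    r_edges = np.linspace(0, grid.geom.radius, grid.nr + 1)
    z_edges = np.linspace(0, grid.geom.height, grid.nz + 1)
    for ax, (attr, label, scale) in zip(axes.ravel(), _PANELS):
        pm = ax.pcolormesh(
            r_edges, z_edges, (getattr(solution, attr) * scale).T, shading="flat"
        )
        fig.colorbar(pm, ax=ax, label=label)
        ax.set_xlabel("r (mm)")
        ax.set_ylabel("z (mm)")
    fig.suptitle(f"Scenario: {solution.scenario.name}")
    return fig
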