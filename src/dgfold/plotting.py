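"""Static interaction-map rendering.

The interaction map is the standard two-triangle view of a folding
problem: the upper triangle shows the target distance matrix (restraint
bound midpoints), the lower triangle the distances realized by the
current conformation, on one shared color ramp.  For a perfectly
satisfied restraint set the two triangles mirror each other.
"""
from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .exceptions import ShapeError
from .formats import RestraintSet
from .geometry import CaTrace, pairwise_distances


def interaction_map_matrix(rs: RestraintSet, trace: CaTrace) -> np.ndarray:
    """The L×L matrix behind the rendering: target midpoints above the
    diagonal, realized distances below, NaN where no restraint exists."""
    if rs.length != len(trace):
        raise ShapeError("restraints and trace lengths differ")
    L = rs.length
    realized = pairwise_distances(trace)
    grid = np.full((L, L), np.nan)
    tril = np.tril_indices(L, k=-1)
    grid[tril] = realized[tril]
    for r in rs.restraints:
        grid[r.i - 1, r.j - 1] = 0.5 * (r.lower + r.upper)
    return grid


def render_interaction_map(rs: RestraintSet, trace: CaTrace, path) -> None:
    """Write the interaction map as a raster image (format from the
    file extension; PNG recommended)."""
    grid = interaction_map_matrix(rs, trace)
    L = rs.length
    fig, ax = plt.subplots(figsize=(6, 5.4))
    im = ax.imshow(grid, cmap="viridis_r", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="distance (Å)")
    ax.set_xlabel("residue (target above diagonal)")
    ax.set_ylabel("residue (model below diagonal)")
    ax.set_title(f"interaction map, L = {L}")
    try:
        fig.savefig(path, dpi=120)
    finally:
        plt.close(fig)
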