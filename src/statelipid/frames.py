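"""Representative-frame selection against a reference occupancy density.

Each candidate frame's instantaneous lipid density (same whole-lipid 3 Å
selection and grid geometry as the reference occupancy grid) is correlated
with the reference; frames are ranked by correlation and accepted greedily
under a per-trajectory cap (default: at most 40% of the requested frames
from any single trajectory) so the selection is not dominated by one run.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .occupancy import (
    PROXIMAL_CUTOFF,
    GridGeometry,
    frame_occupancy,
)
from .trajio import StateLabelTable, Topology, Trajectory, VolumetricGrid

logger = logging.getLogger(__name__)


def frame_density(
    coords: np.ndarray,
    topology: Topology,
    box: np.ndarray,
    reference: VolumetricGrid,
    cutoff: float = PROXIMAL_CUTOFF,
) -> VolumetricGrid:
    """Binary single-frame lipid density on the reference grid's geometry."""
    geometry = GridGeometry(tuple(reference.origin), reference.spacing,
                            reference.shape)
    occ = frame_occupancy(coords, topology, box, geometry, cutoff)
    return VolumetricGrid(reference.origin.copy(), reference.spacing,
                          occ.astype(float))


def density_correlation(
    grid_a: VolumetricGrid,
    grid_b: VolumetricGrid,
    mask: np.ndarray | None = None,
) -> float:
    """Pearson correlation between two grids over a voxel mask.

    The default mask is the union of nonzero voxels of both grids.  Raises
    if either operand is constant over the mask (correlation undefined).
    """
    if not grid_a.same_geometry(grid_b):
        raise ValueError("grids have different origin/spacing/shape")
    a, b = grid_a.values, grid_b.values
    if mask is None:
        mask = (a != 0) | (b != 0)
    av, bv = a[mask], b[mask]
    if av.size == 0 or av.std() == 0 or bv.std() == 0:
        raise ValueError("correlation undefined: zero variance over mask")
    return float(np.corrcoef(av, bv)[0, 1])


def score_frames(
    trajectories: Sequence[Trajectory],
    topology: Topology,
    reference: VolumetricGrid,
    labels: StateLabelTable | None = None,
    state: str | None = None,
    cutoff: float = PROXIMAL_CUTOFF,
) -> pd.DataFrame:
    """Correlation of every candidate frame's density with the reference.

    Candidates are all frames, or only those carrying ``state`` when a label
    table is given.  Frames whose density is empty (no proximal lipids) get
    correlation -inf so they rank last.  Columns: traj_id, frame, correlation.
    """
    rows = []
    for traj in trajectories:
        if labels is not None and state is not None:
            frames = labels.frames_with(traj.traj_id, state)
        else:
            frames = np.arange(traj.n_frames)
        for f in frames:
            dens = frame_density(traj.coords[f], topology, traj.box[f],
                                 reference, cutoff)
            try:
                corr = density_correlation(dens, reference)
            except ValueError:
                corr = -np.inf
            rows.append((traj.traj_id, int(f), corr))
    return pd.DataFrame(rows, columns=["traj_id", "frame", "correlation"])


def select_representative(
    scores: pd.DataFrame,
    n: int = 100,
    per_traj_cap: float = 0.4,
) -> pd.DataFrame:
    """Greedy top-``n`` selection with a per-trajectory quota.

    Frames are sorted by correlation descending (ties: traj_id then frame
    ascending) and accepted in order, skipping any frame whose trajectory
    already holds ``floor(per_traj_cap * n)`` selected frames.  Stops at
    ``n`` or exhaustion (with a warning).  Deterministic for fixed input.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < per_traj_cap <= 1:
        raise ValueError("per_traj_cap must lie in (0, 1]")
    cap = max(int(np.floor(per_traj_cap * n)), 1)
    ordered = scores.sort_values(
        ["correlation", "traj_id", "frame"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    taken: dict[str, int] = {}
    rows = []
    for rec in ordered.itertuples(index=False):
        if len(rows) >= n:
            break
        if taken.get(rec.traj_id, 0) >= cap:
            continue
        taken[rec.traj_id] = taken.get(rec.traj_id, 0) + 1
        rows.append((len(rows) + 1, rec.traj_id, rec.frame, rec.correlation))
    if len(rows) < n:
        logger.warning("only %d of %d requested frames selectable under "
                       "per-trajectory cap %d", len(rows), n, cap)
    return pd.DataFrame(rows,
                        columns=["rank", "traj_id", "frame", "correlation"])
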