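"""State-classified lipid occupancy density grids.

For each conformational state, the frames carrying that state label are
pooled and a regular grid records, per voxel, the fraction of frames in
which the voxel center lies inside any atom sphere of a "proximal" lipid —
a whole lipid with any atom within a cutoff (default 3 Å) of the protein
surface.  Thresholding the grid (default at an occupancy fraction of 0.40)
turns it into a binding-site density; differencing grids between states
highlights state-dependent sites; correlating a grid with its 72° rotations
about the pore axis quantifies five-fold symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .trajio import StateLabelTable, Topology, Trajectory, VolumetricGrid

PROXIMAL_CUTOFF = 3.0  # Å
DEFAULT_SPACING = 1.0  # Å
DEFAULT_THRESHOLD = 0.4


@dataclass(frozen=True)
class GridGeometry:
    """Origin, spacing and shape shared by a family of grids."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def empty(self) -> VolumetricGrid:
        return VolumetricGrid(np.asarray(self.origin), self.spacing,
                              np.zeros(self.shape))


def geometry_for(
    topology: Topology,
    coords: np.ndarray,
    spacing: float = DEFAULT_SPACING,
    margin: float = 8.0,
) -> GridGeometry:
    """Grid geometry covering the protein plus a margin on every side."""
    prot = coords[topology.protein_mask]
    lo = prot.min(axis=0) - margin
    hi = prot.max(axis=0) + margin
    shape = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return GridGeometry(tuple(lo), spacing, shape)  # type: ignore[arg-type]


def select_proximal_lipids(
    coords: np.ndarray,
    topology: Topology,
    box: np.ndarray,
    cutoff: float = PROXIMAL_CUTOFF,
) -> np.ndarray:
    """Lipid molecule ids with any atom within ``cutoff`` of any protein atom.

    Whole-lipid semantics: qualifying molecules are returned as ids and all
    their atoms take part in subsequent density calculations.
    """
    from MDAnalysis.lib.distances import distance_array

    prot = np.flatnonzero(topology.protein_mask)
    lip = np.flatnonzero(topology.lipid_mask)
    if lip.size == 0:
        return np.array([], dtype=int)
    d = distance_array(coords[prot], coords[lip],
                       box=np.array([*box, 90.0, 90.0, 90.0]))
    ids = topology.lipid_id[lip]
    return np.unique(ids[d.min(axis=0) <= cutoff])


def _paint_atoms(
    occ: np.ndarray,
    geometry: GridGeometry,
    centers: np.ndarray,
    radii: np.ndarray,
) -> None:
    """Set voxels whose center falls inside any atom sphere (in place)."""
    origin = np.asarray(geometry.origin)
    s = geometry.spacing
    shape = geometry.shape
    for c, r in zip(centers, radii):
        lo_i = np.maximum(np.ceil((c - r - origin) / s).astype(int), 0)
        hi_i = np.minimum(np.floor((c + r - origin) / s).astype(int),
                          np.array(shape) - 1)
        if np.any(lo_i > hi_i):
            continue
        ax = [origin[k] + s * np.arange(lo_i[k], hi_i[k] + 1) - c[k]
              for k in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        sub = occ[lo_i[0]:hi_i[0] + 1, lo_i[1]:hi_i[1] + 1, lo_i[2]:hi_i[2] + 1]
        sub |= d2 <= r * r


def frame_occupancy(
    coords: np.ndarray,
    topology: Topology,
    box: np.ndarray,
    geometry: GridGeometry,
    cutoff: float = PROXIMAL_CUTOFF,
) -> np.ndarray:
    """Boolean single-frame occupancy of proximal-lipid atoms."""
    occ = np.zeros(geometry.shape, dtype=bool)
    ids = select_proximal_lipids(coords, topology, box, cutoff)
    if ids.size:
        lip_atoms = topology.lipid_atom_indices()
        ai = np.concatenate([lip_atoms[int(l)] for l in ids])
        _paint_atoms(occ, geometry, coords[ai], topology.radius[ai])
    return occ


def occupancy_grid(
    frames: Iterable[tuple[np.ndarray, np.ndarray]],
    topology: Topology,
    geometry: GridGeometry,
    cutoff: float = PROXIMAL_CUTOFF,
    metadata: dict | None = None,
) -> VolumetricGrid:
    """Occupancy-fraction grid over an iterable of ``(coords, box)`` frames.

    Voxel value = fraction of frames in which the voxel center lies inside
    any selected lipid atom's van der Waals sphere; values are in [0, 1].
    """
    counts = np.zeros(geometry.shape, dtype=np.int64)
    n = 0
    for coords, box in frames:
        counts += frame_occupancy(coords, topology, box, geometry, cutoff)
        n += 1
    if n == 0:
        raise ValueError("empty frame set — check the state filter")
    grid = VolumetricGrid(np.asarray(geometry.origin), geometry.spacing,
                          counts / n, metadata or {})
    grid.metadata.setdefault("n_frames", n)
    return grid


def state_frames(
    trajectories: Sequence[Trajectory],
    labels: StateLabelTable,
    state: str,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield ``(coords, box)`` for all frames labelled ``state``."""
    for traj in trajectories:
        for f in labels.frames_with(traj.traj_id, state):
            yield traj.coords[f], traj.box[f]


def state_occupancy_grid(
    trajectories: Sequence[Trajectory],
    labels: StateLabelTable,
    state: str,
    topology: Topology,
    geometry: GridGeometry | None = None,
    spacing: float = DEFAULT_SPACING,
    cutoff: float = PROXIMAL_CUTOFF,
) -> VolumetricGrid:
    """Occupancy grid restricted to frames carrying one state label."""
    if geometry is None:
        geometry = geometry_for(topology, trajectories[0].coords[0], spacing)
    frames = state_frames(trajectories, labels, state)
    try:
        return occupancy_grid(frames, topology, geometry, cutoff,
                              metadata={"state": state})
    except ValueError as exc:
        raise ValueError(f"no frames labelled {state!r}") from exc


def threshold_grid(grid: VolumetricGrid,
                   level: float = DEFAULT_THRESHOLD) -> VolumetricGrid:
    """Binary grid keeping voxels with occupancy >= level (inclusive)."""
    if not 0.0 <= level <= 1.0:
        raise ValueError("threshold level must lie in [0, 1]")
    out = grid.copy()
    out.values = (grid.values >= level).astype(float)
    out.metadata["threshold"] = level
    return out


def state_difference(grid_a: VolumetricGrid,
                     grid_b: VolumetricGrid) -> VolumetricGrid:
    """Voxelwise A - B between two geometrically identical grids."""
    if not grid_a.same_geometry(grid_b):
        raise ValueError("grids have different origin/spacing/shape")
    meta = {
        "difference": (grid_a.metadata.get("state", "A"),
                       grid_b.metadata.get("state", "B")),
    }
    return VolumetricGrid(grid_a.origin.copy(), grid_a.spacing,
                          grid_a.values - grid_b.values, meta)


def _rotate_grid(grid: VolumetricGrid, angle: float,
                 axis_xy: tuple[float, float]) -> np.ndarray:
    """Trilinearly resample the grid rotated by ``angle`` about a z axis."""
    from scipy import ndimage

    c, s = np.cos(angle), np.sin(angle)
    # output[idx] = input[R^T (idx*sp + org - p) + p - org) / sp]
    R_T = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    p = np.array([axis_xy[0], axis_xy[1], 0.0])
    org = grid.origin
    sp = grid.spacing
    offset = (R_T @ (org - p) + p - org) / sp
    return ndimage.affine_transform(grid.values, R_T, offset=offset,
                                    order=1, mode="constant", cval=0.0)


def c5_symmetry_correlation(
    grid: VolumetricGrid,
    axis_xy: tuple[float, float] = (0.0, 0.0),
    n_fold: int = 5,
) -> tuple[np.ndarray, VolumetricGrid]:
    """Correlations of a grid with its k·(360/n)° rotations, plus the
    symmetrized grid.

    Returns the ``n_fold - 1`` Pearson correlations (k = 1..n-1), each over
    the union of nonzero voxels of the two operands, and the mean over all
    ``n_fold`` rotations as the symmetrized grid.
    """
    if n_fold < 2:
        raise ValueError("n_fold must be >= 2")
    vals = grid.values
    acc = vals.copy()
    corrs = []
    for k in range(1, n_fold):
        rot = _rotate_grid(grid, 2 * np.pi * k / n_fold, axis_xy)
        mask = (vals != 0) | (rot != 0)
        if not mask.any() or vals[mask].std() == 0 or rot[mask].std() == 0:
            raise ValueError("grid has no variance over the rotation mask")
        corrs.append(float(np.corrcoef(vals[mask], rot[mask])[0, 1]))
        acc += rot
    sym = VolumetricGrid(grid.origin.copy(), grid.spacing, acc / n_fold,
                         {"symmetrized": n_fold})
    return np.array(corrs), sym
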