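"""State-dependent geometric analyses around the pore axis.

Covers: fitting the channel's symmetry axis, radial statistics of the lipid
atoms closest to the upper pore, lipid penetration probabilities at a radial
threshold, residue-lipid minimum distances and their per-state contact
fractions, projection of a per-frame scalar onto a 2D collective-variable
landscape, a geometric open/closed classifier for the synthetic gate, and
n-fold symmetry expansion of per-subunit records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .trajio import Topology

CONTACT_THRESHOLD = 3.0  # Å


@dataclass
class PoreAxisFrame:
    """Pore symmetry axis plus leaflet slab definitions.

    Slabs are z-intervals relative to the axis origin; by convention the
    membrane normal is z, so the axis is the vertical through the protein
    center of geometry.
    """

    origin: np.ndarray  # (3,)
    axis: np.ndarray  # (3,), unit
    slabs: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if norm == 0:
            raise ValueError("degenerate axis vector")
        self.axis = self.axis / norm
        for name, (lo, hi) in self.slabs.items():
            if not lo < hi:
                raise ValueError(f"slab {name!r} has empty interval")


def define_pore_axis(
    topology: Topology,
    coords: np.ndarray,
    slabs: dict[str, tuple[float, float]] | None = None,
) -> PoreAxisFrame:
    """Axis through the protein center of geometry along the membrane normal.

    Default slabs split the membrane at the axis origin: ``outer`` covers
    z > 0 (extracellular-facing leaflet), ``inner`` z < 0.
    """
    prot = coords[topology.protein_mask]
    if len(prot) < 5:
        raise ValueError("need at least 5 protein atoms to define an axis")
    origin = prot.mean(axis=0)
    if slabs is None:
        slabs = {"outer": (0.0, np.inf), "inner": (-np.inf, 0.0)}
    return PoreAxisFrame(origin, np.array([0.0, 0.0, 1.0]), slabs)


def _slab_lipid_radii(
    coords: np.ndarray,
    topology: Topology,
    axis: PoreAxisFrame,
    slab: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial distances to the axis and azimuths of lipid atoms in a slab."""
    if slab not in axis.slabs:
        raise KeyError(f"unknown slab {slab!r}")
    lo, hi = axis.slabs[slab]
    lip = np.flatnonzero(topology.lipid_mask)
    rel = coords[lip] - axis.origin
    # project out the axis component; axis is unit length
    z = rel @ axis.axis
    in_slab = (z >= lo) & (z <= hi)
    lateral = rel[in_slab] - np.outer(z[in_slab], axis.axis)
    radii = np.linalg.norm(lateral, axis=1)
    phis = np.arctan2(lateral[:, 1], lateral[:, 0])
    return radii, phis


def radial_min_distance(
    coords: np.ndarray,
    topology: Topology,
    axis: PoreAxisFrame,
    slab: str = "outer",
    per_sector: bool = False,
    n_sectors: int = 5,
    sector_offset: float = 0.0,
) -> float | np.ndarray:
    """Minimum radial distance of slab lipid atoms to the pore axis (Å).

    With ``per_sector`` the atoms are partitioned into ``n_sectors`` azimuthal
    wedges (anchored at ``sector_offset`` radians, i.e. the first subunit's
    azimuth) and a per-sector minimum is returned.  Empty slabs or sectors
    yield NaN.
    """
    radii, phis = _slab_lipid_radii(coords, topology, axis, slab)
    if not per_sector:
        return float(radii.min()) if radii.size else float("nan")
    width = 2 * np.pi / n_sectors
    sector = np.floor(((phis - sector_offset + width / 2) % (2 * np.pi))
                      / width).astype(int)
    out = np.full(n_sectors, np.nan)
    for s in range(n_sectors):
        r = radii[sector == s]
        if r.size:
            out[s] = r.min()
    return out


def penetration_fraction(
    min_radii: np.ndarray,
    r_threshold: float,
) -> float:
    """Fraction of frames whose minimum radial lipid distance <= threshold.

    ``min_radii`` is a per-frame array (NaN = no slab lipid in that frame);
    frames without slab lipids are excluded from the denominator.
    """
    r = np.asarray(min_radii, dtype=float)
    valid = ~np.isnan(r)
    if not valid.any():
        return float("nan")
    return float(np.mean(r[valid] <= r_threshold))


def residue_lipid_min_distance(
    coords: np.ndarray,
    topology: Topology,
    residue: tuple[str, int],
    box: np.ndarray,
) -> float:
    """Minimum-image minimum distance from a residue to any lipid atom (Å)."""
    from MDAnalysis.lib.distances import distance_array

    ai = topology.residue_atoms(*residue)
    lip = np.flatnonzero(topology.lipid_mask)
    if lip.size == 0:
        raise ValueError("no lipid atoms in topology")
    d = distance_array(coords[ai], coords[lip],
                       box=np.array([*box, 90.0, 90.0, 90.0]))
    return float(d.min())


def state_contact_fraction(
    distances: np.ndarray,
    labels: np.ndarray,
    threshold: float = CONTACT_THRESHOLD,
) -> dict[str, float]:
    """Per-state fraction of frames with a distance at or below threshold.

    States with zero frames map to NaN.  ``distances`` and ``labels`` are
    aligned per frame.
    """
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if distances.shape != labels.shape:
        raise ValueError("distances and labels must be aligned per frame")
    out: dict[str, float] = {}
    for state in pd.unique(labels):
        sel = labels == state
        out[str(state)] = float(np.mean(distances[sel] <= threshold))
    return out


@dataclass
class LandscapeProjection:
    """Per-bin mean of a scalar over a 2D collective-variable landscape."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    mean: np.ndarray  # (nx, ny), NaN where empty
    counts: np.ndarray  # (nx, ny)

    @property
    def empty_mask(self) -> np.ndarray:
        return self.counts == 0


def landscape_projection(
    cv: np.ndarray,
    scalar: np.ndarray,
    bins: tuple[np.ndarray, np.ndarray],
) -> LandscapeProjection:
    """Bin frames on two collective variables and average a scalar per bin.

    ``cv`` has shape (n_frames, 2); frames outside the bin range are dropped.
    """
    cv = np.asarray(cv, dtype=float)
    scalar = np.asarray(scalar, dtype=float)
    if cv.ndim != 2 or cv.shape[1] != 2 or len(scalar) != len(cv):
        raise ValueError("cv must be (n_frames, 2) aligned with scalar")
    x_edges, y_edges = (np.asarray(b, dtype=float) for b in bins)
    for e in (x_edges, y_edges):
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
    mean, _, _, _ = sp_stats.binned_statistic_2d(
        cv[:, 0], cv[:, 1], scalar, statistic="mean",
        bins=[x_edges, y_edges])
    counts, _, _, _ = sp_stats.binned_statistic_2d(
        cv[:, 0], cv[:, 1], scalar, statistic="count",
        bins=[x_edges, y_edges])
    return LandscapeProjection(x_edges, y_edges, mean, counts.astype(int))


def geometric_state_classifier(
    coords: np.ndarray,
    topology: Topology,
    axis: PoreAxisFrame,
    open_radius: float,
    gate_resname: str = "GAT",
) -> str:
    """Label a frame ``open`` iff the mean gate-bead radius >= open_radius."""
    gate = np.flatnonzero(topology.resname == gate_resname)
    if gate.size == 0:
        raise ValueError(f"no gate atoms with resname {gate_resname!r}")
    rel = coords[gate] - axis.origin
    z = rel @ axis.axis
    lateral = rel - np.outer(z, axis.axis)
    mean_r = float(np.linalg.norm(lateral, axis=1).mean())
    return "open" if mean_r >= open_radius else "closed"


def symmetry_expand(
    records: pd.DataFrame,
    n_fold: int = 5,
    axis_origin: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Expand per-subunit records by n-fold rotation about the pore axis.

    Rotates the ``x, y`` columns by k·(360/n)° for k = 0..n-1, replicating all
    other columns and adding ``sym_copy``; five per-subunit lipid poses thus
    become 25 records on a pentamer.
    """
    if n_fold < 1:
        raise ValueError("n_fold must be >= 1")
    if not {"x", "y"}.issubset(records.columns):
        raise ValueError("records need x and y columns")
    ox, oy = axis_origin
    out = []
    for k in range(n_fold):
        phi = 2 * np.pi * k / n_fold
        c, s = np.cos(phi), np.sin(phi)
        df = records.copy()
        x = records["x"].to_numpy() - ox
        y = records["y"].to_numpy() - oy
        df["x"] = ox + c * x - s * y
        df["y"] = oy + s * x + c * y
        df["sym_copy"] = k
        out.append(df)
    return pd.concat(out, ignore_index=True)
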