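"""Residue-lipid contact series, duration and exchange statistics.

A protein residue and a lipid molecule are "in contact" in a frame when the
minimum-image distance between any atom pair falls at or below a cutoff
(default 4 Å, the conventional interaction cutoff for atomistic
protein-lipid fingerprinting).  Contiguous contact frames form a run; run
lengths (times dt) are the interaction durations, and the number of distinct
lipid molecules ever contacting a residue is its exchange count.

Runs truncated by either trajectory end are kept at their observed length and
flagged as censored — durations of very stable interactions are therefore
lower bounds, as in any finite-trajectory analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajio import Topology, Trajectory

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 4.0  # Å


@dataclass
class ContactSeries:
    """Boolean contact time series per (protein residue, lipid molecule)."""

    residue_keys: list[tuple[str, int, str]]  # (chain, resid, resname)
    lipid_ids: np.ndarray
    series: np.ndarray  # bool, (n_residues, n_lipids, n_frames)
    dt: float  # ns
    cutoff: float  # Å
    traj_id: str = ""

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.series.shape[:2] != (len(self.residue_keys), len(self.lipid_ids)):
            raise ValueError("series shape inconsistent with keys")


@dataclass
class ResidueContactStats:
    """Per-residue contact statistics for one trajectory.

    ``table`` columns: chain, resid, resname, mean_duration_ns, n_runs,
    n_lipids, censored (any run touching a trajectory end).
    """

    table: pd.DataFrame
    dt: float
    traj_id: str = ""


def _group_starts(values: np.ndarray) -> np.ndarray:
    """Start offsets of blocks of equal consecutive values (values sorted)."""
    return np.flatnonzero(np.r_[True, values[1:] != values[:-1]])


def contact_series(
    trajectory: Trajectory,
    topology: Topology,
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactSeries:
    """Compute the residue-lipid contact matrix over all frames.

    Contact iff min over atom pairs of the minimum-image distance <= cutoff,
    evaluated in x, y, z for orthorhombic boxes.
    """
    from MDAnalysis.lib.distances import distance_array

    prot_res = topology.protein_residues()
    if not prot_res:
        raise ValueError("topology contains no protein residues")
    lipid_idx = np.flatnonzero(topology.lipid_mask)
    if lipid_idx.size == 0:
        raise ValueError("topology contains no lipid atoms")

    # order protein atoms by residue and lipid atoms by molecule so that a
    # segmented min (reduceat) collapses the atom-pair distance matrix
    prot_atom_order = np.concatenate([ai for _, _, _, ai in prot_res])
    prot_starts = np.cumsum([0] + [len(ai) for _, _, _, ai in prot_res])[:-1]
    lip_sort = lipid_idx[np.argsort(topology.lipid_id[lipid_idx], kind="stable")]
    lip_ids_sorted = topology.lipid_id[lip_sort]
    lip_starts = _group_starts(lip_ids_sorted)
    lipid_ids = lip_ids_sorted[lip_starts]

    F = trajectory.n_frames
    out = np.empty((len(prot_res), len(lipid_ids), F), dtype=bool)
    for f in range(F):
        d = distance_array(
            trajectory.coords[f, prot_atom_order],
            trajectory.coords[f, lip_sort],
            box=trajectory.mda_box(f),
        )
        d = np.minimum.reduceat(d, prot_starts, axis=0)
        d = np.minimum.reduceat(d, lip_starts, axis=1)
        out[:, :, f] = d <= cutoff

    keys = [(chain, resid, resname) for chain, resid, resname, _ in prot_res]
    return ContactSeries(keys, lipid_ids, out, trajectory.dt, cutoff,
                         trajectory.traj_id)


def _runs_from_bool(vec: np.ndarray, gap_tolerance: int) -> tuple[list[int], bool]:
    """Run lengths (frames) after merging gaps <= gap_tolerance; censored flag.

    Merged gaps are counted into the run duration (run spans first to last
    contact frame of the merged block).
    """
    idx = np.flatnonzero(vec)
    if idx.size == 0:
        return [], False
    split_at = np.flatnonzero(np.diff(idx) > gap_tolerance + 1) + 1
    groups = np.split(idx, split_at)
    runs = [int(g[-1] - g[0] + 1) for g in groups]
    censored = bool(idx[0] == 0 or idx[-1] == len(vec) - 1)
    return runs, censored


def duration_stats(
    series: ContactSeries, gap_tolerance: int = 0
) -> ResidueContactStats:
    """Per-residue mean contact duration, run count and distinct-lipid count.

    Mean duration is the mean of all run lengths (x dt) pooled over lipid
    partners; residues without contacts get mean 0 and 0 runs.
    """
    if series.series.shape[2] == 0:
        raise ValueError("empty contact series")
    rows = []
    any_contact = series.series.any(axis=2)
    for ri, (chain, resid, resname) in enumerate(series.residue_keys):
        run_lengths: list[int] = []
        censored = False
        partners = np.flatnonzero(any_contact[ri])
        for li in partners:
            runs, cens = _runs_from_bool(series.series[ri, li], gap_tolerance)
            run_lengths.extend(runs)
            censored = censored or cens
        mean_dur = float(np.mean(run_lengths) * series.dt) if run_lengths else 0.0
        rows.append({
            "chain": chain,
            "resid": resid,
            "resname": resname,
            "mean_duration_ns": mean_dur,
            "n_runs": len(run_lengths),
            "n_lipids": int(partners.size),
            "censored": censored,
        })
    return ResidueContactStats(pd.DataFrame(rows), series.dt, series.traj_id)


def exchange_counts(series: ContactSeries) -> pd.DataFrame:
    """Distinct lipid molecules contacting each residue over the trajectory."""
    counts = series.series.any(axis=2).sum(axis=1)
    return pd.DataFrame({
        "chain": [k[0] for k in series.residue_keys],
        "resid": [k[1] for k in series.residue_keys],
        "resname": [k[2] for k in series.residue_keys],
        "n_lipids": counts.astype(int),
    })


def aggregate_ensemble(
    stats: list[ResidueContactStats], pool_subunits: bool = False
) -> pd.DataFrame:
    """Ensemble mean of per-trajectory contact statistics.

    Residues are matched by ``(chain, resid)``, or by ``resid`` alone when
    ``pool_subunits`` is set — the chains of a symmetric homopentamer then
    contribute as independent samples.  Returns one row per residue key with
    ensemble means, the sample count, and the retained per-sample values.
    """
    if not stats:
        raise ValueError("need at least one trajectory's statistics")
    frames = []
    for s in stats:
        df = s.table.copy()
        df["traj_id"] = s.traj_id
        frames.append(df)
    allstats = pd.concat(frames, ignore_index=True)
    keys = ["resid"] if pool_subunits else ["chain", "resid"]
    grouped = allstats.groupby(keys, sort=True)
    out = grouped.agg(
        resname=("resname", "first"),
        mean_duration_ns=("mean_duration_ns", "mean"),
        mean_n_runs=("n_runs", "mean"),
        mean_n_lipids=("n_lipids", "mean"),
        n_samples=("mean_duration_ns", "size"),
        any_censored=("censored", "any"),
    ).reset_index()
    samples = grouped["mean_duration_ns"].apply(list).reset_index(
        name="duration_samples"
    )
    return out.merge(samples, on=keys)
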