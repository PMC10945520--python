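"""End-to-end orchestration of the analysis stages from a single config.

``run_pipeline`` executes the enabled stages in dependency order
(io -> contacts/diffusion -> occupancy -> frame selection -> geometry),
writes every output as plain text (TSV tables, OpenDX grids, PDB snapshots)
into the output directory, and records a manifest of inputs, parameters and
output checksums.  Identical config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as ca
from . import diffusion as da
from . import frames as fs
from . import geometry as ga
from . import occupancy as oc
from . import synthetic as syn
from . import trajio

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "contacts", "diffusion", "occupancy",
              "select_frames", "geometry")

FLOAT_FMT = "%.8g"


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline once, reproducibly."""

    outdir: str = "statelipid_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    synthetic: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # topology/trajectories/labels
    contact_cutoff: float = 4.0
    gap_tolerance: int = 0
    shell_cutoff: float = 4.0
    proximal_cutoff: float = 3.0
    spacing: float = 1.0
    threshold: float = 0.4
    n_select: int = 100
    per_traj_cap: float = 0.4
    fit_window: tuple[float, float] = (0.1, 0.5)
    states: tuple[str, str] = ("closed", "open")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.stages = tuple(cfg.stages)
        cfg.fit_window = tuple(cfg.fit_window)  # type: ignore[assignment]
        cfg.states = tuple(cfg.states)  # type: ignore[assignment]
        return cfg

    def synthetic_config(self) -> syn.SyntheticConfig:
        raw = dict(self.synthetic)
        sites = [syn.SiteSpec(**{**s, "states_active":
                                 tuple(s.get("states_active",
                                             ("closed", "open")))})
                 for s in raw.pop("site_specs", [])]
        sched = raw.pop("state_schedule", None)
        if sched is not None:
            sched = tuple((int(a), int(b), str(lbl)) for a, b, lbl in sched)
        return syn.SyntheticConfig(site_specs=tuple(sites),
                                   state_schedule=sched,
                                   seed=self.seed, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return the output manifest."""
    import MDAnalysis

    from . import __version__

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {k: v for k, v in asdict(config).items()},
        "versions": {
            "statelipid": __version__,
            "numpy": np.__version__,
            "MDAnalysis": MDAnalysis.__version__,
        },
        "stages": {},
        "outputs": {},
    }
    produced: list[Path] = []
    state: dict = {}

    def record(path: Path) -> None:
        produced.append(path)

    def run_stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            (out / f"{name}.failed").write_text(str(exc))
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        logger.info("stage %s done in %.2fs", name,
                    time.perf_counter() - t0)

    # ---- io / simulate -----------------------------------------------------
    def stage_simulate():
        if config.inputs:
            top = trajio.read_topology(config.inputs["topology"])
            trajs = [
                trajio.read_trajectory(p, top,
                                       topology_path=config.inputs["topology"],
                                       traj_id=Path(p).stem)
                for p in config.inputs["trajectories"]
            ]
            labels = trajio.read_state_labels(config.inputs["labels"])
            state.update(topology=top, trajectories=trajs, labels=labels)
            return
        sim = syn.simulate(config.synthetic_config())
        state.update(topology=sim.topology, trajectories=[sim.trajectory],
                     labels=sim.labels, sim=sim)
        top_path = out / "system.pdb"
        trajio.write_topology(sim.topology, sim.trajectory.coords[0],
                              sim.trajectory.box[0], top_path)
        record(top_path)
        lbl_path = out / "labels.tsv"
        trajio.write_state_labels(sim.labels, lbl_path)
        record(lbl_path)
        gt = sim.ground_truth
        gt_df = pd.DataFrame({
            "site": range(len(gt.mean_residence_ns)),
            "mean_residence_ns": gt.mean_residence_ns,
            "bound_fraction": gt.bound_fraction,
        })
        gt_df["D_free_nm2_per_us"] = gt.D_free
        gt_path = out / "ground_truth.tsv"
        _write_tsv(gt_df, gt_path)
        record(gt_path)

    # ---- contacts ----------------------------------------------------------
    def stage_contacts():
        rows = []
        for traj in state["trajectories"]:
            series = ca.contact_series(traj, state["topology"],
                                       config.contact_cutoff)
            stats = ca.duration_stats(series, config.gap_tolerance)
            df = stats.table.copy()
            df.insert(0, "traj_id", traj.traj_id)
            rows.append(df)
            state.setdefault("contact_stats", []).append(stats)
        path = out / "contact_stats.tsv"
        _write_tsv(pd.concat(rows, ignore_index=True), path)
        record(path)

    # ---- diffusion ---------------------------------------------------------
    def stage_diffusion():
        top = state["topology"]
        est_rows = []
        for traj in state["trajectories"]:
            shell, bulk = da.assign_shells(traj.coords[0], top, traj.box[0],
                                           config.shell_cutoff)
            for label, ids in (("first_shell", shell), ("bulk", bulk)):
                if len(ids) == 0:
                    continue
                msd = da.lateral_msd(traj, top, ids, set_label=label)
                est = da.fit_diffusion(msd, config.fit_window)
                est_rows.append({
                    "traj_id": traj.traj_id, "set": label, "n_lipids": len(ids),
                    "D_nm2_per_us": est.D, "slope_A2_per_ns": est.slope,
                    "r_squared": est.r_squared,
                    "window_lo_ns": est.window_ns[0],
                    "window_hi_ns": est.window_ns[1],
                })
                curve = pd.DataFrame({"lag_ns": msd.lags_ns, "msd_A2": msd.msd,
                                      "n_pairs": msd.n_pairs})
                cpath = out / f"msd_{traj.traj_id}_{label}.tsv"
                _write_tsv(curve, cpath)
                record(cpath)
        path = out / "diffusion.tsv"
        _write_tsv(pd.DataFrame(est_rows), path)
        record(path)

    # ---- occupancy ---------------------------------------------------------
    def stage_occupancy():
        top = state["topology"]
        trajs = state["trajectories"]
        geometry = oc.geometry_for(top, trajs[0].coords[0], config.spacing)
        grids = {}
        sym_rows = []
        for st in config.states:
            try:
                grid = oc.state_occupancy_grid(
                    trajs, state["labels"], st, top, geometry,
                    cutoff=config.proximal_cutoff)
            except ValueError:
                logger.warning("no frames labelled %r; skipping grid", st)
                continue
            grids[st] = grid
            gpath = out / f"occupancy_{st}.dx"
            trajio.write_grid(grid, gpath)
            record(gpath)
            tpath = out / f"occupancy_{st}_thresholded.dx"
            trajio.write_grid(oc.threshold_grid(grid, config.threshold), tpath)
            record(tpath)
            try:
                corrs, _ = oc.c5_symmetry_correlation(grid)
                sym_rows.append({"state": st,
                                 **{f"corr_{72 * (k + 1)}deg": c
                                    for k, c in enumerate(corrs)}})
            except ValueError:
                pass
        if len(grids) == 2:
            a, b = (grids[s] for s in config.states[::-1])  # open - closed
            dpath = out / "occupancy_difference.dx"
            trajio.write_grid(oc.state_difference(a, b), dpath)
            record(dpath)
        if sym_rows:
            spath = out / "symmetry_correlations.tsv"
            _write_tsv(pd.DataFrame(sym_rows), spath)
            record(spath)
        state["grids"] = grids

    # ---- frame selection ---------------------------------------------------
    def stage_select_frames():
        grids = state.get("grids")
        if not grids:
            raise ValueError(
                "frame selection requires a reference occupancy grid; "
                "enable the occupancy stage"
            )
        top = state["topology"]
        for st, grid in grids.items():
            scores = fs.score_frames(state["trajectories"], top, grid,
                                     state["labels"], st,
                                     config.proximal_cutoff)
            sel = fs.select_representative(scores, config.n_select,
                                           config.per_traj_cap)
            path = out / f"selected_frames_{st}.tsv"
            _write_tsv(sel, path)
            record(path)

    # ---- geometry ----------------------------------------------------------
    def stage_geometry():
        top = state["topology"]
        rows = []
        for traj in state["trajectories"]:
            axis = ga.define_pore_axis(top, traj.coords[0])
            labels = state["labels"].labels_for(traj.traj_id, traj.n_frames)
            radii = np.array([
                ga.radial_min_distance(traj.coords[f], top, axis, "outer")
                for f in range(traj.n_frames)
            ])
            for st in config.states:
                sel = labels == st
                if not sel.any():
                    continue
                rows.append({
                    "traj_id": traj.traj_id, "state": st,
                    "n_frames": int(sel.sum()),
                    "median_min_radius_A": float(np.nanmedian(radii[sel])),
                })
        path = out / "radial_by_state.tsv"
        _write_tsv(pd.DataFrame(rows), path)
        record(path)

    run_stage("simulate", stage_simulate)
    run_stage("contacts", stage_contacts)
    run_stage("diffusion", stage_diffusion)
    run_stage("occupancy", stage_occupancy)
    run_stage("select_frames", stage_select_frames)
    run_stage("geometry", stage_geometry)

    for path in produced:
        manifest["outputs"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
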