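"""Shared fixtures: synthetic systems at the sizes the estimators assume.

Simulations are session-scoped because several test modules interrogate the
same ground-truth system from different angles.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import statelipid as sl
from statelipid.trajio import Topology, Trajectory

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def kin_sim() -> sl.SimulationResult:
    """Five slow binding sites (1/k_off = 100 ns) sampled over 8 µs."""
    sites = tuple(sl.SiteSpec(subunit=k, k_off=0.01) for k in range(5))
    cfg = sl.SyntheticConfig(
        n_lipids_per_leaflet=30, n_frames=8000, box=120.0,
        site_specs=sites, seed=7,
    )
    return sl.simulate(cfg)


@pytest.fixture(scope="session")
def gated_sim() -> sl.SimulationResult:
    """Open-gated surface and deep sites under an alternating state schedule."""
    sched = ((0, 500, "closed"), (500, 1000, "open"),
             (1000, 1500, "closed"), (1500, 2000, "open"))
    phi = 2 * np.pi * 2 / 5
    sites = (
        sl.SiteSpec(subunit=0, k_off=0.02, states_active=("open",)),
        sl.SiteSpec(subunit=2, k_off=0.02, states_active=("open",),
                    anchor_xy=(13 * np.cos(phi), 13 * np.sin(phi)),
                    capture_radius=6.0),
    )
    cfg = sl.SyntheticConfig(
        n_lipids_per_leaflet=20, n_frames=2000, box=120.0,
        site_specs=sites, state_schedule=sched, seed=5,
    )
    return sl.simulate(cfg)


@pytest.fixture(scope="session")
def diff_sim() -> sl.SimulationResult:
    """Site-free bilayer at the size the diffusion estimator assumes."""
    cfg = sl.SyntheticConfig(
        n_lipids_per_leaflet=140, n_frames=1000, box=180.0,
        D_free=1.0, seed=0,
    )
    return sl.simulate(cfg)


@pytest.fixture(scope="session")
def tiny_sim() -> sl.SimulationResult:
    """Small fast system for I/O and plumbing tests."""
    cfg = sl.SyntheticConfig(n_lipids_per_leaflet=10, n_frames=5, box=120.0,
                             seed=0)
    return sl.simulate(cfg)


def point_system(
    protein: list[tuple[str, int, np.ndarray]],
    lipids: list[list[np.ndarray]],
    box: tuple[float, float, float] = (100.0, 100.0, 100.0),
    radius: float = 1.7,
) -> tuple[Topology, Trajectory]:
    """One-frame system from explicit bead positions.

    ``protein``: (chain, resid, xyz) per protein bead; ``lipids``: list of
    per-molecule bead position lists.
    """
    resid, resname, chain, name, kind, lipid_id, coords = [], [], [], [], [], [], []
    for ch, ri, pos in protein:
        resid.append(ri); resname.append("SCF"); chain.append(ch)
        name.append("BB"); kind.append("protein"); lipid_id.append(-1)
        coords.append(np.asarray(pos, dtype=float))
    for li, beads in enumerate(lipids):
        for b, pos in enumerate(beads):
            resid.append(li + 1); resname.append("POPC"); chain.append("L")
            name.append(f"B{b}"); kind.append("lipid"); lipid_id.append(li)
            coords.append(np.asarray(pos, dtype=float))
    top = Topology(
        np.array(resid), np.array(resname, dtype=object),
        np.array(chain, dtype=object), np.array(name, dtype=object),
        np.array(kind, dtype=object), np.array(lipid_id),
        np.full(len(resid), radius),
    )
    traj = Trajectory(
        "point", np.asarray(coords)[None, :, :],
        np.asarray(box, dtype=float)[None, :], dt=1.0,
    )
    return top, traj
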