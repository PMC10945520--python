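"""Occupancy grids: selection, fractions, thresholds, differences, symmetry."""

import numpy as np
import pytest

import statelipid as sl
from statelipid.occupancy import GridGeometry, frame_occupancy
from statelipid.trajio import VolumetricGrid

from conftest import point_system


class TestProximalSelection:
    def test_whole_lipid_rule(self):
        top, traj = point_system(
            [("A", 1, (0, 0, 0))],
            [[(2.5, 0, 0), (12, 0, 0)], [(20, 0, 0), (21, 0, 0)]],
        )
        ids = sl.select_proximal_lipids(traj.coords[0], top, traj.box[0],
                                        cutoff=3.0)
        assert ids.tolist() == [0]  # head qualifies, whole molecule selected

    def test_cutoff_excludes_far_lipid(self):
        top, traj = point_system([("A", 1, (0, 0, 0))], [[(3.5, 0, 0)]])
        assert sl.select_proximal_lipids(traj.coords[0], top, traj.box[0],
                                         cutoff=3.0).size == 0

    def test_selection_monotone_in_cutoff(self, gated_sim):
        coords = gated_sim.trajectory.coords[700]
        box = gated_sim.trajectory.box[700]
        at3 = set(sl.select_proximal_lipids(coords, gated_sim.topology, box, 3.0))
        at4 = set(sl.select_proximal_lipids(coords, gated_sim.topology, box, 4.0))
        assert at3 <= at4


class TestOccupancyGrid:
    @pytest.fixture()
    def fixed_atom_system(self):
        top, traj = point_system([("A", 1, (0, 0, 0))], [[(2.0, 0, 0)]])
        geom = GridGeometry((-5.0, -5.0, -5.0), 1.0, (11, 11, 11))
        return top, traj, geom

    def test_always_present_atom_gives_unity(self, fixed_atom_system):
        top, traj, geom = fixed_atom_system
        frames = [(traj.coords[0], traj.box[0])] * 10
        grid = sl.occupancy_grid(frames, top, geom)
        # voxel at the atom center (index 7, 5, 5)
        assert grid.values[7, 5, 5] == 1.0
        assert grid.values.min() >= 0 and grid.values.max() <= 1

    def test_fractional_presence(self, fixed_atom_system):
        top, traj, geom = fixed_atom_system
        away = traj.coords[0].copy()
        away[1] = (40.0, 40.0, 40.0)  # outside the 3 Å selection
        frames = [(traj.coords[0], traj.box[0])] * 4 + \
                 [(away, traj.box[0])] * 6
        grid = sl.occupancy_grid(frames, top, geom)
        assert grid.values[7, 5, 5] == pytest.approx(0.4)

    def test_empty_frame_set_names_filter(self, gated_sim):
        with pytest.raises(ValueError, match="desensitized"):
            sl.state_occupancy_grid(
                [gated_sim.trajectory],
                sl.StateLabelTable(gated_sim.labels.table,
                                   (*gated_sim.labels.vocabulary,
                                    "desensitized")),
                "desensitized", gated_sim.topology,
            )

    def test_additive_over_frame_subsets(self, gated_sim):
        """State grids recombine into the all-frame grid by frame count."""
        top = gated_sim.topology
        traj = gated_sim.trajectory
        geom = sl.geometry_for(top, traj.coords[0])
        g_closed = sl.state_occupancy_grid([traj], gated_sim.labels, "closed",
                                           top, geom)
        g_open = sl.state_occupancy_grid([traj], gated_sim.labels, "open",
                                         top, geom)
        n_c = g_closed.metadata["n_frames"]
        n_o = g_open.metadata["n_frames"]
        g_all = sl.occupancy_grid(
            ((traj.coords[f], traj.box[f]) for f in range(traj.n_frames)),
            top, geom)
        combined = (n_c * g_closed.values + n_o * g_open.values) / (n_c + n_o)
        assert np.allclose(combined, g_all.values, atol=1e-12)

    def test_invariant_to_frame_order(self, gated_sim):
        top = gated_sim.topology
        traj = gated_sim.trajectory
        geom = sl.geometry_for(top, traj.coords[0])
        sel = list(range(0, 100, 10))
        fwd = sl.occupancy_grid(((traj.coords[f], traj.box[f]) for f in sel),
                                top, geom)
        rev = sl.occupancy_grid(
            ((traj.coords[f], traj.box[f]) for f in reversed(sel)), top, geom)
        assert np.array_equal(fwd.values, rev.values)


class TestThreshold:
    def test_inclusive_at_level(self):
        g = VolumetricGrid(np.zeros(3), 1.0,
                           np.array([[[0.39, 0.40, 0.41]]]))
        kept = sl.threshold_grid(g, 0.4)
        assert kept.values.ravel().tolist() == [0.0, 1.0, 1.0]

    def test_lower_level_keeps_superset(self, gated_sim):
        top, traj = gated_sim.topology, gated_sim.trajectory
        geom = sl.geometry_for(top, traj.coords[0])
        g = sl.state_occupancy_grid([traj], gated_sim.labels, "open", top, geom)
        at30 = sl.threshold_grid(g, 0.3).values > 0
        at40 = sl.threshold_grid(g, 0.4).values > 0
        assert np.all(at40 <= at30)

    def test_invalid_level_rejected(self):
        g = VolumetricGrid(np.zeros(3), 1.0, np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            sl.threshold_grid(g, 1.2)


class TestStateDifference:
    def test_antisymmetry_and_identity(self):
        rng = np.random.default_rng(0)
        a = VolumetricGrid(np.zeros(3), 1.0, rng.random((4, 4, 4)))
        b = VolumetricGrid(np.zeros(3), 1.0, rng.random((4, 4, 4)))
        zero = VolumetricGrid(np.zeros(3), 1.0, np.zeros((4, 4, 4)))
        assert np.allclose(sl.state_difference(a, b).values,
                           -sl.state_difference(b, a).values)
        assert np.allclose(sl.state_difference(a, zero).values, a.values)
        assert np.allclose(sl.state_difference(a, a).values, 0.0)

    def test_geometry_mismatch_rejected(self):
        a = VolumetricGrid(np.zeros(3), 1.0, np.zeros((4, 4, 4)))
        b = VolumetricGrid(np.ones(3), 1.0, np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            sl.state_difference(a, b)

    def test_open_gated_site_peaks_inside_capture_radius(self, gated_sim):
        """The open-minus-closed density maximum falls at an open-only site."""
        top, traj = gated_sim.topology, gated_sim.trajectory
        geom = sl.geometry_for(top, traj.coords[0])
        g_c = sl.state_occupancy_grid([traj], gated_sim.labels, "closed",
                                      top, geom)
        g_o = sl.state_occupancy_grid([traj], gated_sim.labels, "open",
                                      top, geom)
        diff = sl.state_difference(g_o, g_c)
        peak_idx = np.unravel_index(np.argmax(diff.values), diff.values.shape)
        peak_xyz = diff.origin + diff.spacing * np.array(peak_idx)
        # sites pin lipids laterally while beads span z: compare in x, y
        dists = [
            np.hypot(*(peak_xyz[:2] - np.asarray(s.anchor_xy)))
            - s.capture_radius
            for s in gated_sim.config.resolved_sites()
        ]
        assert min(dists) <= 0


class TestC5Symmetry:
    @staticmethod
    def c5_grid(n=60, spacing=1.0):
        """Analytically five-fold-symmetric grid centred on the axis."""
        half = (n - 1) / 2 * spacing
        ax = np.linspace(-half, half, n)
        x, y, z = np.meshgrid(ax, ax, ax[:20], indexing="ij")
        r = np.hypot(x, y)
        phi = np.arctan2(y, x)
        vals = np.exp(-((r - 15) / 4) ** 2) * (1 + np.cos(5 * phi)) / 2
        vals[vals < 1e-3] = 0.0
        return VolumetricGrid(np.array([-half, -half, -half]), spacing, vals)

    def test_symmetric_grid_correlates_near_unity(self):
        corrs, _ = sl.c5_symmetry_correlation(self.c5_grid())
        assert np.all(corrs >= 0.98)

    def test_random_grid_uncorrelated(self):
        rng = np.random.default_rng(1)
        g = VolumetricGrid(np.array([-30.0, -30.0, -10.0]), 1.0,
                           rng.random((61, 61, 30)))
        corrs, _ = sl.c5_symmetry_correlation(g)
        assert np.all(np.abs(corrs) < 0.1)

    def test_symmetrize_idempotent(self):
        g = self.c5_grid()
        _, sym1 = sl.c5_symmetry_correlation(g)
        _, sym2 = sl.c5_symmetry_correlation(sym1)
        scale = g.values.max()
        assert np.abs(sym2.values - sym1.values).max() <= 0.05 * scale

    def test_degenerate_grid_rejected(self):
        g = VolumetricGrid(np.zeros(3), 1.0, np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            sl.c5_symmetry_correlation(g)
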