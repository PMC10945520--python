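"""Pore-axis geometry, penetration statistics and landscape projection."""

import numpy as np
import pytest

import statelipid as sl
from statelipid.geometry import PoreAxisFrame

from conftest import point_system


@pytest.fixture(scope="module")
def symmetric_axis():
    cfg = sl.SyntheticConfig(n_lipids_per_leaflet=10, n_frames=2, seed=0)
    sim = sl.simulate(cfg)
    return sim, sl.define_pore_axis(sim.topology, sim.trajectory.coords[0])


class TestPoreAxis:
    def test_passes_through_symmetry_center(self, symmetric_axis):
        _, axis = symmetric_axis
        assert np.hypot(axis.origin[0], axis.origin[1]) < 0.1
        assert np.linalg.norm(axis.axis) == pytest.approx(1.0)

    def test_translation_equivariance(self, symmetric_axis):
        sim, axis = symmetric_axis
        shift = np.array([3.0, -7.0, 11.0])
        moved = sl.define_pore_axis(sim.topology,
                                    sim.trajectory.coords[0] + shift)
        assert np.allclose(moved.origin, axis.origin + shift)

    def test_too_few_atoms_rejected(self):
        top, traj = point_system([("A", 1, (0, 0, 0))], [[(5, 0, 0)]])
        with pytest.raises(ValueError):
            sl.define_pore_axis(top, traj.coords[0])

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            PoreAxisFrame(np.zeros(3), np.zeros(3))


class TestRadialMinDistance:
    def axis(self):
        return PoreAxisFrame(np.zeros(3), np.array([0, 0, 1.0]),
                             {"outer": (0.0, np.inf), "inner": (-np.inf, 0.0)})

    def test_single_atom_radius(self):
        top, traj = point_system([("A", 1, (0, 0, 0))] * 5, [[(20.0, 0, 5.0)]])
        r = sl.radial_min_distance(traj.coords[0], top, self.axis(), "outer")
        assert r == pytest.approx(20.0)

    def test_minimum_of_two(self):
        top, traj = point_system(
            [("A", 1, (0, 0, 0))] * 5,
            [[(18.0, 0, 5.0)], [(0, 25.0, 5.0)]],
        )
        r = sl.radial_min_distance(traj.coords[0], top, self.axis(), "outer")
        assert r == pytest.approx(18.0)

    def test_empty_slab_is_missing(self):
        top, traj = point_system([("A", 1, (0, 0, 0))] * 5, [[(18.0, 0, 5.0)]])
        r = sl.radial_min_distance(traj.coords[0], top, self.axis(), "inner")
        assert np.isnan(r)

    def test_per_sector_partition(self):
        top, traj = point_system(
            [("A", 1, (0, 0, 0))] * 5,
            [[(18.0, 0.0, 5.0)], [(-20.0, 1.0, 5.0)]],
        )
        out = sl.radial_min_distance(traj.coords[0], top, self.axis(), "outer",
                                     per_sector=True, n_sectors=4)
        assert out[0] == pytest.approx(18.0)
        assert out[2] == pytest.approx(np.hypot(20.0, 1.0))
        assert np.isnan(out[1]) and np.isnan(out[3])

    def test_rigid_rotation_invariance(self, symmetric_axis):
        sim, axis = symmetric_axis
        coords = sim.trajectory.coords[1]
        r0 = sl.radial_min_distance(coords, sim.topology, axis, "outer")
        phi = 1.1
        R = np.array([[np.cos(phi), -np.sin(phi), 0],
                      [np.sin(phi), np.cos(phi), 0], [0, 0, 1.0]])
        rot = coords @ R.T
        axis_rot = sl.define_pore_axis(sim.topology, rot)
        r1 = sl.radial_min_distance(rot, sim.topology, axis_rot, "outer")
        assert r1 == pytest.approx(r0, abs=1e-6)


class TestPenetrationFraction:
    def test_counts_frames_at_or_below_threshold(self):
        radii = np.array([10.0, 15.0, 20.0, 12.0, np.nan])
        assert sl.penetration_fraction(radii, 14.0) == pytest.approx(2 / 4)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        radii = rng.uniform(5, 30, 100)
        fr = [sl.penetration_fraction(radii, t) for t in (10, 15, 20, 25)]
        assert fr == sorted(fr)

    def test_infinite_threshold_saturates(self):
        assert sl.penetration_fraction(np.array([3.0, 99.0]), np.inf) == 1.0

    def test_open_gated_deep_site_increases_penetration(self, gated_sim):
        """Deep lipid density appears only in open-state frames."""
        top, traj = gated_sim.topology, gated_sim.trajectory
        axis = sl.define_pore_axis(top, traj.coords[0])
        labels = gated_sim.config.state_labels()
        radii = np.array([
            sl.radial_min_distance(traj.coords[f], top, axis, "outer")
            for f in range(traj.n_frames)
        ])
        p_open = sl.penetration_fraction(radii[labels == "open"], 15.0)
        p_closed = sl.penetration_fraction(radii[labels == "closed"], 15.0)
        assert p_open > p_closed


class TestResidueLipidDistance:
    def test_minimum_over_pairs(self):
        top, traj = point_system(
            [("A", 1, (0, 0, 0))], [[(2.9, 0, 0), (9.0, 0, 0)]],
        )
        d = sl.residue_lipid_min_distance(traj.coords[0], top, ("A", 1),
                                          traj.box[0])
        assert d == pytest.approx(2.9)

    def test_unknown_residue_rejected(self):
        top, traj = point_system([("A", 1, (0, 0, 0))], [[(5, 0, 0)]])
        with pytest.raises(KeyError):
            sl.residue_lipid_min_distance(traj.coords[0], top, ("Z", 9),
                                          traj.box[0])


class TestStateContactFraction:
    def test_per_state_fractions(self):
        d = np.array([2.5, 2.8, 3.5, 5.0])
        labels = np.array(["open", "open", "open", "closed"], dtype=object)
        fr = sl.state_contact_fraction(d, labels, threshold=3.0)
        assert fr["open"] == pytest.approx(2 / 3)
        assert fr["closed"] == 0.0

    def test_open_gated_site_contacts_only_open(self, gated_sim):
        top, traj = gated_sim.topology, gated_sim.trajectory
        labels = gated_sim.config.state_labels()
        d = np.array([
            sl.residue_lipid_min_distance(traj.coords[f], top, ("A", 200),
                                          traj.box[f])
            for f in range(traj.n_frames)
        ])
        fr = sl.state_contact_fraction(d, labels, threshold=3.0)
        assert fr["open"] > fr["closed"]
        assert fr["closed"] == 0.0


class TestLandscapeProjection:
    def test_single_bin_mean(self):
        cv = np.tile([0.5, 0.5], (10, 1))
        proj = sl.landscape_projection(cv, np.full(10, 3.0),
                                       (np.array([0, 1, 2.0]),
                                        np.array([0, 1, 2.0])))
        assert proj.mean[0, 0] == pytest.approx(3.0)
        assert proj.counts[0, 0] == 10
        assert proj.empty_mask.sum() == 3

    def test_constant_scalar_everywhere(self):
        rng = np.random.default_rng(1)
        cv = rng.uniform(0, 1, size=(200, 2))
        proj = sl.landscape_projection(cv, np.full(200, 7.5),
                                       (np.linspace(0, 1, 5),
                                        np.linspace(0, 1, 5)))
        assert np.allclose(proj.mean[~proj.empty_mask], 7.5)
        assert proj.counts.sum() == 200

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError):
            sl.landscape_projection(np.zeros((3, 2)), np.zeros(3),
                                    (np.array([0, 0.0]), np.array([0, 1.0])))


class TestGeometricClassifier:
    def test_threshold_inclusive(self):
        cfg = sl.SyntheticConfig(n_lipids_per_leaflet=10, n_frames=2,
                                 gate_radius_closed=4.0, seed=0)
        sim = sl.simulate(cfg)
        axis = sl.define_pore_axis(sim.topology, sim.trajectory.coords[0])
        label = sl.geometric_state_classifier(sim.trajectory.coords[0],
                                              sim.topology, axis,
                                              open_radius=4.0)
        assert label == "open"  # radius exactly at the threshold counts open

    def test_recovers_generating_schedule(self, gated_sim):
        top, traj = gated_sim.topology, gated_sim.trajectory
        axis = sl.define_pore_axis(top, traj.coords[0])
        predicted = np.array([
            sl.geometric_state_classifier(traj.coords[f], top, axis, 4.5)
            for f in range(traj.n_frames)
        ])
        assert (predicted == gated_sim.config.state_labels()).all()


class TestSymmetryExpand:
    def test_five_poses_give_25_records(self):
        import pandas as pd

        poses = pd.DataFrame({
            "x": [19.0, 18.0, 17.5, 19.5, 18.2],
            "y": [0.0, 1.0, -1.0, 0.5, -0.5],
            "z": [19.0] * 5,
            "pose": list("abcde"),
        })
        expanded = sl.symmetry_expand(poses, n_fold=5)
        assert len(expanded) == 25
        assert set(expanded.sym_copy) == set(range(5))
        # radius from the axis is preserved by every rotation
        r0 = np.hypot(poses.x, poses.y)
        r = np.hypot(expanded.x, expanded.y)
        assert np.allclose(np.sort(r), np.sort(np.tile(r0, 5)))

    def test_requires_coordinates(self):
        import pandas as pd

        with pytest.raises(ValueError):
            sl.symmetry_expand(pd.DataFrame({"a": [1]}), n_fold=5)
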