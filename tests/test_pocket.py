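"""Trajectory pocket analysis: contacts, hulls, H-bonds, SASA, maps."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from flimcrowd.pocket import (
    PocketDefinition,
    Trajectory,
    count_hydrogen_bonds,
    define_pocket,
    distance_difference_map,
    pocket_volume,
    pocket_volume_distribution,
    residue_contacts,
    sasa_shrake_rupley,
    trim_equilibration,
)
from flimcrowd.simulate import ToyTrajectorySpec, generate_toy_trajectory


def _ca_atoms(n):
    return pd.DataFrame(
        {
            "residue_index": np.arange(n),
            "residue_name": "ALA",
            "atom_name": "CA",
            "element": "C",
        }
    )


class TestTrim:
    def test_first_quarter_dropped(self):
        traj = Trajectory(np.zeros((100, 3, 3)), _ca_atoms(3))
        assert trim_equilibration(traj, 0.25).n_frames == 75

    def test_zero_fraction_identity(self):
        traj = Trajectory(np.zeros((10, 3, 3)), _ca_atoms(3))
        assert trim_equilibration(traj, 0.0).n_frames == 10

    def test_ceiling_convention(self):
        traj = Trajectory(np.zeros((5, 3, 3)), _ca_atoms(3))
        assert trim_equilibration(traj, 0.25).n_frames == 3  # ceil(1.25) = 2 dropped

    def test_empty_result_rejected(self):
        traj = Trajectory(np.zeros((4, 3, 3)), _ca_atoms(3))
        with pytest.raises(ValueError):
            trim_equilibration(traj, 0.99)


class TestContacts:
    def test_cutoff_boundary(self):
        atoms = _ca_atoms(2)
        near = np.array([[0.0, 0, 0], [3.4, 0, 0]])
        far = np.array([[0.0, 0, 0], [3.6, 0, 0]])
        assert (0, 1) in residue_contacts(near, atoms, [0], [1])
        assert residue_contacts(far, atoms, [0], [1]) == set()

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 10, (30, 3))
        atoms = _ca_atoms(30)
        sel_a, sel_b = list(range(15)), list(range(15, 30))
        before = residue_contacts(frame, atoms, sel_a, sel_b)
        rot = Rotation.random(random_state=1).as_matrix()
        after = residue_contacts(frame @ rot.T + np.array([5.0, -3.0, 2.0]), atoms, sel_a, sel_b)
        assert before == after

    def test_kdtree_equals_brute_force(self):
        rng = np.random.default_rng(2)
        frame = rng.uniform(0, 12, (500, 3))
        atoms = _ca_atoms(500)
        sel_a, sel_b = list(range(250)), list(range(250, 500))
        fast = residue_contacts(frame, atoms, sel_a, sel_b)
        brute = set()
        for i in sel_a:
            for j in sel_b:
                if np.linalg.norm(frame[i] - frame[j]) < 3.5:
                    brute.add((i, j))
        assert fast == brute


class TestDefinePocket:
    def _ensemble_with_planted_contacts(self, n_frames=1000, touch_frames=1):
        """Residue 1 touches the target in `touch_frames` frames; residue 2
        always touches; residue 3 never."""
        coords = np.zeros((n_frames, 4, 3))
        coords[:, 1] = [10.0, 0, 0]
        coords[:touch_frames, 1] = [2.0, 0, 0]
        coords[:, 2] = [0, 2.0, 0]
        coords[:, 3] = [0, 0, 20.0]
        return [Trajectory(coords, _ca_atoms(4))]

    def test_rare_contact_excluded_frequent_included(self):
        ens = self._ensemble_with_planted_contacts(n_frames=1000, touch_frames=1)
        pocket = define_pocket(ens, target_residues=[0])
        # 0.1% < 0.33% threshold: excluded; permanent contact: included
        assert 1 not in pocket.pocket_residues
        assert 2 in pocket.pocket_residues
        assert 3 not in pocket.pocket_residues

    def test_contact_just_above_threshold_included(self):
        ens = self._ensemble_with_planted_contacts(n_frames=1000, touch_frames=4)
        pocket = define_pocket(ens, target_residues=[0])
        assert 1 in pocket.pocket_residues  # 0.4% > 0.33%

    def test_missing_target_rejected(self):
        ens = self._ensemble_with_planted_contacts()
        with pytest.raises(ValueError, match="target"):
            define_pocket(ens, target_residues=[99])


class TestPocketVolume:
    def test_unit_tetrahedron(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        pocket = PocketDefinition([], np.arange(4))
        assert pocket_volume(pts, _ca_atoms(4), pocket) == pytest.approx(1.0 / 6.0)

    def test_cube_and_interior_point_invariance(self):
        cube = np.array(
            [[x, y, z] for x in (0, 2.0) for y in (0, 2.0) for z in (0, 2.0)]
        )
        pocket8 = PocketDefinition([], np.arange(8))
        v8 = pocket_volume(cube, _ca_atoms(8), pocket8)
        assert v8 == pytest.approx(8.0)
        with_center = np.vstack([cube, [[1.0, 1.0, 1.0]]])
        pocket9 = PocketDefinition([], np.arange(9))
        assert pocket_volume(with_center, _ca_atoms(9), pocket9) == pytest.approx(8.0)

    def test_degenerate_coplanar_zero(self):
        flat = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        pocket = PocketDefinition([], np.arange(4))
        assert pocket_volume(flat, _ca_atoms(4), pocket) == 0.0

    def test_hull_volume_matches_monte_carlo(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 3.0, (50, 3))
        pocket = PocketDefinition([], np.arange(50))
        v = pocket_volume(pts, _ca_atoms(50), pocket)
        from scipy.spatial import Delaunay

        lo, hi = pts.min(0), pts.max(0)
        samples = rng.uniform(lo, hi, (1_000_000, 3))
        inside = Delaunay(pts).find_simplex(samples) >= 0
        v_mc = inside.mean() * np.prod(hi - lo)
        assert abs(v - v_mc) / v < 0.01

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 2.0, (20, 3))
        pocket = PocketDefinition([], np.arange(20))
        v1 = pocket_volume(pts, _ca_atoms(20), pocket)
        rot = Rotation.random(random_state=5).as_matrix()
        v2 = pocket_volume(pts @ rot.T + 7.0, _ca_atoms(20), pocket)
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_hull_monotone_under_added_points(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 2.0, (12, 3))
        v1 = pocket_volume(pts, _ca_atoms(12), PocketDefinition([], np.arange(12)))
        more = np.vstack([pts, rng.normal(0, 2.0, (3, 3))])
        v2 = pocket_volume(more, _ca_atoms(15), PocketDefinition([], np.arange(15)))
        assert v2 >= v1 - 1e-12


class TestVolumeDistribution:
    def _two_state_ensembles(self):
        pocket_idx = list(range(0, 3)) + list(range(13, 16)) + list(range(25, 28))
        def make(offset, seed):
            spec = ToyTrajectorySpec(
                n_residues=36,
                n_frames=20,
                pocket_residue_indices=pocket_idx,
                pocket_expansion_per_state=(offset,),
                thermal_noise_sd=0.1,
                seed=seed,
            )
            coords, _ = generate_toy_trajectory(spec)
            return Trajectory.from_calpha(coords)
        pocket = PocketDefinition([], np.array(pocket_idx))
        comp = [make(0.0, s) for s in range(3)]
        expa = [make(1.5, 10 + s) for s in range(3)]
        return comp, expa, pocket

    def test_expanded_state_dominates(self):
        comp, expa, pocket = self._two_state_ensembles()
        d_comp = pocket_volume_distribution(comp, pocket)
        d_expa = pocket_volume_distribution(expa, pocket)
        assert d_expa.grand_mean > d_comp.grand_mean
        # stochastic dominance of per-frame volumes
        q = np.linspace(0.1, 0.9, 9)
        vc = np.concatenate(d_comp.per_frame)
        ve = np.concatenate(d_expa.per_frame)
        assert np.all(np.quantile(ve, q) >= np.quantile(vc, q))

    def test_identical_replicas_zero_sem(self):
        comp, _, pocket = self._two_state_ensembles()
        dist = pocket_volume_distribution([comp[0], comp[0]], pocket)
        assert dist.sem == 0.0

    def test_sem_is_replica_sd_over_sqrt_n(self):
        comp, _, pocket = self._two_state_ensembles()
        dist = pocket_volume_distribution(comp, pocket)
        manual = dist.replica_means.std(ddof=1) / np.sqrt(dist.replica_means.size)
        assert dist.sem == pytest.approx(manual)

    def test_single_replica_sem_nan(self):
        comp, _, pocket = self._two_state_ensembles()
        dist = pocket_volume_distribution([comp[0]], pocket)
        assert np.isnan(dist.sem)


class TestDistanceDifferenceMap:
    def test_self_difference_zero(self):
        rng = np.random.default_rng(8)
        traj = Trajectory.from_calpha(rng.normal(0, 5, (4, 10, 3)))
        d = distance_difference_map([traj], [traj], list(range(10)))
        assert np.allclose(d, 0.0)

    def test_uniform_expansion_positive_and_antisymmetric(self):
        spec = dict(
            n_residues=24,
            n_frames=4,
            pocket_residue_indices=list(range(24)),
            thermal_noise_sd=0.0,
            seed=0,
        )
        c0, _ = generate_toy_trajectory(
            ToyTrajectorySpec(pocket_expansion_per_state=(0.0,), **spec)
        )
        c1, _ = generate_toy_trajectory(
            ToyTrajectorySpec(pocket_expansion_per_state=(1.0,), **spec)
        )
        a, b = Trajectory.from_calpha(c1), Trajectory.from_calpha(c0)
        # restrict to one ring: uniform radial expansion separates all pairs
        ring = list(range(12))
        d = distance_difference_map([a], [b], ring)
        off = ~np.eye(len(ring), dtype=bool)
        assert np.all(d[off] > 0)
        np.testing.assert_allclose(
            d, -distance_difference_map([b], [a], ring), atol=1e-12
        )
        assert np.allclose(d, d.T)


class TestHydrogenBonds:
    def test_geometric_criteria(self):
        # ideal linear: D at origin, H at 1 A, A at 2.9 A along x
        linear = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]])
        assert count_hydrogen_bonds(linear, [0], [1], [2]) == 1
        # 120 degrees at the hydrogen: excluded by the 150-degree cutoff
        ang = np.deg2rad(180 - 120)
        bent = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [1.0 + 1.9 * np.cos(ang), 1.9 * np.sin(ang), 0]]
        )
        assert count_hydrogen_bonds(bent, [0], [1], [2]) == 0
        # too long: 3.6 A donor-acceptor
        long = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.6, 0, 0]])
        assert count_hydrogen_bonds(long, [0], [1], [2]) == 0

    def test_unpaired_hydrogen_rejected(self):
        frame = np.zeros((3, 3))
        with pytest.raises(ValueError, match="paired"):
            count_hydrogen_bonds(frame, [0], [1, 2], [2])


class TestSasa:
    def test_isolated_atom_analytic(self):
        atoms = _ca_atoms(1)
        s = sasa_shrake_rupley(np.zeros((1, 3)), atoms)
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert abs(s.iloc[0] - expected) / expected < 0.01

    def test_buried_atom_near_zero(self):
        # central atom enclosed by a tight icosahedral-ish shell
        shell = []
        for th in np.linspace(0, np.pi, 8):
            for ph in np.linspace(0, 2 * np.pi, 12, endpoint=False):
                shell.append(
                    2.0 * np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
                )
        frame = np.vstack([[0.0, 0, 0], shell])
        atoms = _ca_atoms(frame.shape[0])
        s = sasa_shrake_rupley(frame, atoms)
        assert s.iloc[0] < 1.0

    def test_two_atom_overlap_matches_spherical_caps(self):
        d = 2.0
        frame = np.array([[0.0, 0, 0], [d, 0, 0]])
        atoms = pd.DataFrame(
            {
                "residue_index": [0, 1],
                "residue_name": "ALA",
                "atom_name": "CA",
                "element": ["C", "C"],
            }
        )
        s = sasa_shrake_rupley(frame, atoms)
        r = 1.70 + 1.4
        cap_area = 2 * np.pi * r * (r - d / 2.0)  # removed cap per sphere
        expected = 4 * np.pi * r**2 - cap_area
        assert abs(s.iloc[0] - expected) / expected < 0.02

    def test_unknown_element_listed(self):
        atoms = pd.DataFrame(
            {
                "residue_index": [0],
                "residue_name": "UNK",
                "atom_name": "X",
                "element": ["Xx"],
            }
        )
        with pytest.raises(ValueError, match="Xx"):
            sasa_shrake_rupley(np.zeros((1, 3)), atoms)
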