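import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcagedyn import (
    AtomRecord,
    ContactSpec,
    DihedralSpec,
    RingSelection,
    Trajectory,
    centroid_distance_series,
    classify_rotamer,
    cluster_coverage_count,
    contact_occupancy,
    count_multiple_hbonds,
    dihedral_series,
    segment_rmsd_vs_reference,
    summarize_distribution,
)
from tcagedyn.descriptors import rotamer_fractions
from oracles import kabsch_superpose, leader_cluster_sizes, rmsd, torsion_atan2


def traj_from(atoms, coords) -> Trajectory:
    return Trajectory(atoms=atoms, coords=np.asarray(coords, float))


def ring_atoms(chain, res, ring, origin):
    """Topology + one frame of a 4-atom 'ring' around an origin."""
    atoms = [AtomRecord(name, "TRP", res, chain) for name in ring]
    offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float)
    return atoms, offsets + np.asarray(origin, float)


class TestCentroidDistance:
    RING = ("CG", "CD1", "CD2", "NE1")

    def _two_ring_traj(self, origin_b):
        atoms_a, xyz_a = ring_atoms("A", 25, self.RING, (0, 0, 0))
        atoms_b, xyz_b = ring_atoms("R", 214, self.RING, origin_b)
        return traj_from(atoms_a + atoms_b, [np.vstack([xyz_a, xyz_b])])

    def test_identical_selections_give_zero(self):
        traj = self._two_ring_traj((9, 9, 9))
        sel = RingSelection("A", 25, self.RING)
        assert centroid_distance_series(traj, sel, sel)[0] == 0.0

    def test_translated_ring_gives_pythagorean_distance(self):
        traj = self._two_ring_traj((3, 4, 0))
        d = centroid_distance_series(traj, RingSelection("A", 25, self.RING),
                                     RingSelection("R", 214, self.RING))
        assert d[0] == pytest.approx(5.0, abs=1e-12)

    def test_matches_brute_force_on_random_coords(self):
        rng = np.random.default_rng(0)
        atoms_a, _ = ring_atoms("A", 25, self.RING, (0, 0, 0))
        atoms_b, _ = ring_atoms("R", 214, self.RING, (0, 0, 0))
        coords = rng.uniform(-10, 10, size=(20, 8, 3))
        traj = traj_from(atoms_a + atoms_b, coords)
        d = centroid_distance_series(traj, RingSelection("A", 25, self.RING),
                                     RingSelection("R", 214, self.RING))
        for f in range(20):
            mean_a = coords[f, :4].sum(axis=0) / 4
            mean_b = coords[f, 4:].sum(axis=0) / 4
            expect = float(np.sqrt(((mean_a - mean_b) ** 2).sum()))
            assert d[f] == pytest.approx(expect, abs=1e-10)

    def test_missing_ring_atom_named(self):
        traj = self._two_ring_traj((1, 1, 1))
        with pytest.raises(KeyError, match="CZ2"):
            centroid_distance_series(
                traj, RingSelection("A", 25, self.RING + ("CZ2",)),
                RingSelection("R", 214, self.RING))


class TestSummarizeDistribution:
    def test_odd_series_median(self):
        s = summarize_distribution(np.array([1.0, 2.0, 3.0]), bin_width=1.0)
        assert s.median == 2.0

    def test_mode_is_most_populated_bin_center(self):
        s = summarize_distribution(np.array([1.0, 1.0, 2.0, 9.0]), bin_width=1.0)
        assert s.mode == pytest.approx(1.0)

    def test_gaussian_sample_mode_and_median_converge(self):
        draws = np.random.default_rng(3).normal(5.4, 0.5, size=100_000)
        s = summarize_distribution(draws, bin_width=0.2)
        assert abs(s.mode - 5.4) <= 0.2
        assert abs(s.median - 5.4) <= 0.01

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            summarize_distribution(np.array([]))


class TestDihedrals:
    def _quad_traj(self, quads):
        atoms = [AtomRecord(n, "TRP", 214, "R") for n in ("N", "CA", "CB", "CG")]
        return traj_from(atoms, quads), DihedralSpec(
            tuple(("R", 214, n) for n in ("N", "CA", "CB", "CG")))

    def test_planar_trans_is_180(self):
        quad = [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]]
        traj, spec = self._quad_traj([quad])
        assert abs(dihedral_series(traj, spec)[0]) == pytest.approx(180.0)

    def test_mirror_image_negates_angle(self):
        rng = np.random.default_rng(1)
        quad = rng.uniform(-5, 5, size=(4, 3))
        mirror = quad * np.array([1.0, 1.0, -1.0])
        traj, spec = self._quad_traj([quad, mirror])
        angles = dihedral_series(traj, spec)
        assert angles[1] == pytest.approx(-angles[0], abs=1e-8)

    def test_matches_independent_atan2_oracle(self):
        rng = np.random.default_rng(7)
        quads = rng.uniform(-8, 8, size=(10_000, 4, 3))
        traj, spec = self._quad_traj(quads)
        angles = dihedral_series(traj, spec)
        expected = np.array([torsion_atan2(*q) for q in quads])
        np.testing.assert_allclose(angles, expected, atol=1e-8)

    def test_cross_check_against_mdanalysis(self):
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(8)
        quads = rng.uniform(-8, 8, size=(500, 4, 3))
        traj, spec = self._quad_traj(quads)
        angles = dihedral_series(traj, spec)
        mda = np.degrees(calc_dihedrals(quads[:, 0], quads[:, 1],
                                        quads[:, 2], quads[:, 3]))
        # compare on the circle (both conventions may emit ±180)
        diff = np.abs(((angles - mda) + 180) % 360 - 180)
        assert diff.max() < 1e-3

    def test_collinear_atoms_yield_nan(self):
        quad = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]]
        traj, spec = self._quad_traj([quad])
        assert np.isnan(dihedral_series(traj, spec)[0])


class TestRotamers:
    @pytest.mark.parametrize("angle,expected", [
        (-60.0, "gauche_minus"),
        (60.0, "gauche_plus"),
        (180.0, "antiperiplanar"),
        (-180.0, "antiperiplanar"),
        (300.0, "gauche_minus"),   # normalizes to -60
        (-120.0, "gauche_minus"),  # sector boundary
        (120.0, "antiperiplanar"),
        (0.0, "gauche_plus"),
    ])
    def test_canonical_angles(self, angle, expected):
        assert classify_rotamer(angle) == expected

    @settings(max_examples=300, deadline=None)
    @given(st.floats(-720, 720, allow_nan=False))
    def test_partition_and_periodicity(self, angle):
        from hypothesis import assume

        # sector boundaries are half-open; stay off them by a float epsilon
        normalized = (angle + 180.0) % 360.0 - 180.0
        assume(min(abs(normalized - b) for b in (-180, -120, 0, 120, 180))
               > 1e-6)
        cls = classify_rotamer(angle)
        assert cls in {"gauche_minus", "gauche_plus", "antiperiplanar"}
        assert classify_rotamer(angle + 360.0) == cls

    def test_fractions_sum_to_one(self):
        fr = rotamer_fractions(np.array([-60.0, -65.0, 170.0, 55.0]))
        assert sum(fr.values()) == pytest.approx(1.0)
        assert fr["gauche_minus"] == pytest.approx(0.5)


def hbond_traj(distances, with_h=True):
    """One donor (N, H) and one acceptor O per frame, aligned on x with a
    straight 180° D-H...A geometry at the given heavy-atom distances."""
    atoms = [AtomRecord("N", "TRP", 25, "A"), AtomRecord("H", "TRP", 25, "A"),
             AtomRecord("O", "ARG", 35, "A")]
    frames = []
    for d in distances:
        frames.append([[0, 0, 0], [1.0, 0, 0], [d, 0, 0]])
    return traj_from(atoms, frames)


class TestContactOccupancy:
    SPEC = ContactSpec(kind="hbond",
                       donors=((("A", 25, "N"), ("A", 25, "H")),),
                       acceptors=(("A", 35, "O"),))

    def test_constructed_five_of_ten(self):
        traj = hbond_traj([3.0] * 5 + [6.0] * 5)
        assert contact_occupancy(traj, self.SPEC).fraction == 0.5

    def test_all_and_none(self):
        assert contact_occupancy(hbond_traj([3.0] * 4), self.SPEC).fraction == 1.0
        assert contact_occupancy(hbond_traj([9.0] * 4), self.SPEC).fraction == 0.0

    def test_angle_criterion_rejects_bent_geometry(self):
        atoms = [AtomRecord("N", "TRP", 25, "A"), AtomRecord("H", "TRP", 25, "A"),
                 AtomRecord("O", "ARG", 35, "A")]
        # acceptor at 90° from the N-H direction as seen from H
        traj = traj_from(atoms, [[[0, 0, 0], [1, 0, 0], [1, 2.0, 0]]])
        assert contact_occupancy(traj, self.SPEC).fraction == 0.0

    def test_multi_pair_matches_brute_force(self):
        rng = np.random.default_rng(4)
        donors, acceptors, atoms = [], [], []
        for i in range(3):
            atoms.append(AtomRecord("NZ", "LYS", 10 + i, "A"))
            donors.append(("A", 10 + i, "NZ"))
        for i in range(2):
            atoms.append(AtomRecord("OD1", "ASP", 28 + i, "A"))
            acceptors.append(("A", 28 + i, "OD1"))
        coords = rng.uniform(0, 8, size=(50, 5, 3))
        traj = traj_from(atoms, coords)
        spec = ContactSpec(kind="saltbridge", donors=tuple(donors),
                           acceptors=tuple(acceptors), distance_cutoff=4.0)
        got = contact_occupancy(traj, spec).fraction
        expect = 0
        for f in range(50):
            hit = any(np.linalg.norm(coords[f, i] - coords[f, 3 + j]) <= 4.0
                      for i in range(3) for j in range(2))
            expect += hit
        assert got == pytest.approx(expect / 50)

    def test_equilibration_discard_drops_leading_frames(self):
        traj = hbond_traj([9.0] * 5 + [3.0] * 5)
        occ = contact_occupancy(traj, self.SPEC, equilibration_discard=0.5)
        assert occ.fraction == 1.0
        assert occ.n_frames == 5


class TestCountMultipleHbonds:
    def test_k1_reduces_to_contact_occupancy(self):
        traj = hbond_traj([3.0] * 3 + [6.0] * 7)
        spec = TestContactOccupancy.SPEC
        assert count_multiple_hbonds(traj, spec, k=1).fraction == \
            contact_occupancy(traj, spec).fraction

    def test_two_simultaneous_pairs_counted(self):
        atoms = [AtomRecord("N", "GLY", 1, "A"), AtomRecord("H", "GLY", 1, "A"),
                 AtomRecord("N", "GLY", 2, "A"), AtomRecord("H", "GLY", 2, "A"),
                 AtomRecord("O", "ASP", 9, "A"), AtomRecord("O", "ASP", 10, "A")]
        # both donors straight onto both acceptors in frame 0; far in frame 1
        near = [[0, 0, 0], [1, 0, 0], [0, 5, 0], [1, 5, 0],
                [3.0, 0, 0], [3.0, 5, 0]]
        far = [[0, 0, 0], [1, 0, 0], [0, 5, 0], [1, 5, 0],
               [30, 0, 0], [30, 5, 0]]
        traj = traj_from(atoms, [near, far])
        spec = ContactSpec(
            kind="hbond",
            donors=((("A", 1, "N"), ("A", 1, "H")), (("A", 2, "N"), ("A", 2, "H"))),
            acceptors=(("A", 9, "O"), ("A", 10, "O")))
        assert count_multiple_hbonds(traj, spec, k=2).fraction == 0.5


class TestSegmentRmsd:
    def _ca_traj(self, coords):
        n = coords.shape[1]
        atoms = [AtomRecord("CA", "ALA", i + 1, "A") for i in range(n)]
        return traj_from(atoms, coords)

    def test_identical_single_frame_gives_zero(self):
        coords = np.random.default_rng(0).uniform(-5, 5, size=(1, 10, 3))
        traj = self._ca_traj(coords)
        sel_fit = [("A", i, "CA") for i in range(1, 6)]
        sel_mea = [("A", i, "CA") for i in range(6, 11)]
        assert segment_rmsd_vs_reference(traj, traj, sel_fit, sel_mea) == \
            pytest.approx(0.0, abs=1e-10)

    def test_rigid_offset_of_measured_region(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(-5, 5, size=(10, 3))
        moved = base.copy()
        moved[5:] += np.array([2.0, 0.0, 0.0])
        ref = self._ca_traj(base[None])
        traj = self._ca_traj(moved[None])
        sel_fit = [("A", i, "CA") for i in range(1, 6)]
        sel_mea = [("A", i, "CA") for i in range(6, 11)]
        assert segment_rmsd_vs_reference(traj, ref, sel_fit, sel_mea) == \
            pytest.approx(2.0, abs=1e-8)

    def test_matches_brute_force_kabsch(self):
        rng = np.random.default_rng(2)
        ref_coords = rng.uniform(-5, 5, size=(1, 12, 3))
        traj_coords = rng.uniform(-5, 5, size=(4, 12, 3))
        ref = self._ca_traj(ref_coords)
        traj = self._ca_traj(traj_coords)
        sel_fit = [("A", i, "CA") for i in range(1, 7)]
        sel_mea = [("A", i, "CA") for i in range(7, 13)]
        got = segment_rmsd_vs_reference(traj, ref, sel_fit, sel_mea)
        vals = []
        for f in range(4):
            apply = kabsch_superpose(traj_coords[f, :6], ref_coords[0, :6])
            vals.append(rmsd(apply(traj_coords[f, 6:]), ref_coords[0, 6:]))
        assert got == pytest.approx(np.mean(vals), abs=1e-8)

    def test_invariant_to_global_rotation_of_frame(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        coords = rng.uniform(-5, 5, size=(1, 10, 3))
        ref = self._ca_traj(coords)
        rot = Rotation.from_euler("xyz", [20, -40, 75], degrees=True)
        rotated = rot.apply(coords[0]) + np.array([3.0, -1.0, 9.0])
        traj = self._ca_traj(rotated[None])
        sel_fit = [("A", i, "CA") for i in range(1, 6)]
        sel_mea = [("A", i, "CA") for i in range(6, 11)]
        assert segment_rmsd_vs_reference(traj, ref, sel_fit, sel_mea) == \
            pytest.approx(0.0, abs=1e-8)


class TestClusterCoverage:
    def _conformer_traj(self, populations, separation=20.0, spread=0.1,
                        n_res=10, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        base = rng.uniform(-3, 3, size=(n_res, 3))
        for c, pop in enumerate(populations):
            center = base + np.array([separation * c, 0.0, 0.0]) * \
                np.linspace(1, 2, n_res)[:, None]  # non-rigid: survives fitting
            for _ in range(pop):
                frames.append(center + rng.normal(0, spread, size=(n_res, 3)))
        atoms = [AtomRecord("CA", "ALA", i + 1, "A") for i in range(n_res)]
        return traj_from(atoms, frames)

    def test_all_identical_frames_one_cluster(self):
        coords = np.tile(np.random.default_rng(0).uniform(-3, 3, (1, 8, 3)),
                         (20, 1, 1))
        atoms = [AtomRecord("CA", "ALA", i + 1, "A") for i in range(8)]
        assert cluster_coverage_count(traj_from(atoms, coords), 1.0) == 1

    def test_96_4_two_state_needs_one_cluster(self):
        traj = self._conformer_traj([96, 4])
        assert cluster_coverage_count(traj, rmsd_cutoff=2.0) == 1

    def test_50_30_20_three_state_needs_three(self):
        traj = self._conformer_traj([50, 30, 20])
        assert cluster_coverage_count(traj, rmsd_cutoff=2.0) == 3

    def test_matches_brute_force_leader_clustering(self):
        from tcagedyn.descriptors import _pairwise_ca_rmsd

        traj = self._conformer_traj([12, 8, 5], separation=8.0, spread=0.8,
                                    seed=3)
        matrix = _pairwise_ca_rmsd(traj)
        sizes = leader_cluster_sizes(matrix, cutoff=2.0)
        needed, cum = 0, 0
        for s in sizes:
            needed += 1
            cum += s
            if cum >= 0.95 * traj.n_frames:
                break
        assert cluster_coverage_count(traj, rmsd_cutoff=2.0) == needed
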