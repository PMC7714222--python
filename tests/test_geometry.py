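import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dgfold.exceptions import (ChainTooShortError, DegenerateGeometryError,
                               InsufficientPointsError, InvalidAngleError,
                               ResidueIndexError)
from dgfold.geometry import (CaTrace, InternalCoords, cartesian_to_internal,
                             internal_to_cartesian, kabsch_superpose,
                             mirror_trace, pairwise_distances,
                             set_residue_angles)

from conftest import random_chain


def wrap(a):
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


class TestInternalToCartesian:
    def test_two_residues_bond_length(self):
        t = internal_to_cartesian(InternalCoords([3.8], [], []))
        assert len(t) == 2
        assert np.linalg.norm(t.coords[1] - t.coords[0]) == pytest.approx(3.8)

    def test_three_residues_law_of_cosines(self):
        t = internal_to_cartesian(InternalCoords([3.8, 3.8], [90.0], []))
        assert np.linalg.norm(t.coords[2] - t.coords[0]) == pytest.approx(
            3.8 * np.sqrt(2.0), abs=1e-9
        )

    def test_zero_dihedral_is_planar(self):
        t = internal_to_cartesian(
            InternalCoords([3.8] * 3, [120.0, 120.0], [0.0])
        )
        # tetrahedron volume of the four points vanishes
        v = t.coords[1:] - t.coords[0]
        assert abs(np.linalg.det(v)) < 1e-9

    def test_invalid_planar_angle_rejected(self):
        with pytest.raises(InvalidAngleError):
            InternalCoords([3.8, 3.8], [180.0], [])

    def test_shape_mismatch_rejected(self):
        from dgfold.exceptions import ShapeError

        with pytest.raises(ShapeError):
            InternalCoords([3.8, 3.8, 3.8], [90.0], [10.0, 20.0])

    def test_canonical_frame(self, rng):
        t = random_chain(rng, 12)
        X = t.coords
        assert np.allclose(X[0], 0.0)
        assert X[1, 1] == 0.0 and X[1, 2] == 0.0 and X[1, 0] > 0
        assert X[2, 2] == pytest.approx(0.0, abs=1e-12)
        assert X[2, 1] > 0

    def test_deterministic_bitwise(self, rng):
        ic = cartesian_to_internal(random_chain(rng, 15))
        a = internal_to_cartesian(ic).coords
        b = internal_to_cartesian(ic).coords
        assert np.array_equal(a, b)


class TestCartesianToInternal:
    def test_round_trip_angles(self):
        ic = InternalCoords([3.8] * 3, [90.0, 90.0], [55.0])
        back = cartesian_to_internal(internal_to_cartesian(ic))
        assert back.planar_angles == pytest.approx([90.0, 90.0], abs=1e-9)
        assert back.dihedral_angles == pytest.approx([55.0], abs=1e-9)

    def test_collinear_trace_rejected(self):
        t = CaTrace([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            cartesian_to_internal(t)

    def test_rigid_motion_invariance(self, rng):
        t = random_chain(rng, 10)
        R = Rotation.from_rotvec([0.4, -0.2, 1.1])
        moved = CaTrace(R.apply(t.coords) + np.array([1.0, -7.0, 2.5]))
        a, b = cartesian_to_internal(t), cartesian_to_internal(moved)
        assert a.bond_lengths == pytest.approx(b.bond_lengths, abs=1e-9)
        assert a.planar_angles == pytest.approx(b.planar_angles, abs=1e-9)
        assert wrap(a.dihedral_angles - b.dihedral_angles) == pytest.approx(
            np.zeros(len(t) - 3), abs=1e-9
        )

    @pytest.mark.parametrize("L", [4, 7, 23])
    def test_round_trip_preserves_distances(self, rng, L):
        # property: Cartesian -> internal -> Cartesian is a rigid motion
        for _ in range(34):
            t = random_chain(rng, L)
            back = internal_to_cartesian(cartesian_to_internal(t))
            assert np.allclose(pairwise_distances(t),
                               pairwise_distances(back), atol=1e-9)


class TestSetResidueAngles:
    def test_identity_manipulation(self, rng):
        t = random_chain(rng, 8)
        ic = cartesian_to_internal(t)
        out = set_residue_angles(t, 3, theta=float(ic.planar_angles[2]),
                                 tau=float(ic.dihedral_angles[1]))
        assert np.allclose(pairwise_distances(out), pairwise_distances(t),
                           atol=1e-9)

    def test_upstream_residues_fixed(self, rng):
        t = random_chain(rng, 10)
        out = set_residue_angles(t, 5, theta=100.0, tau=-60.0)
        assert np.array_equal(out.coords[:5], t.coords[:5])
        ic = cartesian_to_internal(out)
        assert ic.planar_angles[4] == pytest.approx(100.0, abs=1e-9)
        assert ic.dihedral_angles[3] == pytest.approx(-60.0, abs=1e-9)

    def test_first_dihedral_flip_moves_r3_not_r2(self):
        # oracle: explicit coordinates of a 5-residue chain with tau_0 = 0
        ic = InternalCoords([3.8] * 4, [100.0] * 3, [0.0, 90.0])
        t = internal_to_cartesian(ic)
        out = set_residue_angles(t, 2, tau=180.0)
        d02 = np.linalg.norm(t.coords[2] - t.coords[0])
        d03_before = np.linalg.norm(t.coords[3] - t.coords[0])
        assert np.linalg.norm(out.coords[2] - out.coords[0]) == pytest.approx(
            d02, abs=1e-9
        )
        assert abs(np.linalg.norm(out.coords[3] - out.coords[0])
                   - d03_before) > 0.5

    def test_out_of_range_residue(self, rng):
        t = random_chain(rng, 6)
        with pytest.raises(ResidueIndexError):
            set_residue_angles(t, 0, theta=90.0)
        with pytest.raises(ResidueIndexError):
            set_residue_angles(t, 1, tau=10.0)

    def test_invalid_theta(self, rng):
        t = random_chain(rng, 6)
        with pytest.raises(InvalidAngleError):
            set_residue_angles(t, 2, theta=181.0)


class TestMirror:
    def test_involution(self, rng):
        t = random_chain(rng, 9)
        assert np.array_equal(mirror_trace(mirror_trace(t)).coords, t.coords)

    def test_isometry(self, rng):
        t = random_chain(rng, 9)
        assert np.allclose(pairwise_distances(mirror_trace(t)),
                           pairwise_distances(t), atol=1e-12)

    def test_negates_dihedrals(self):
        ic = InternalCoords([3.8] * 9, [91.0] * 8, [50.0] * 7)
        t = internal_to_cartesian(ic)
        back = cartesian_to_internal(mirror_trace(t))
        assert back.dihedral_angles == pytest.approx([-50.0] * 7, abs=1e-9)


class TestKabsch:
    def test_identity(self, rng):
        t = random_chain(rng, 8)
        assert kabsch_superpose(t, t).rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed(self, rng):
        t = random_chain(rng, 8)
        R = Rotation.from_rotvec([1.0, 0.1, -0.6])
        moved = CaTrace(R.apply(t.coords) + np.array([3.0, 4.0, 5.0]))
        sup = kabsch_superpose(moved, t)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.apply(moved.coords), t.coords, atol=1e-9)

    def test_mirror_not_removable(self):
        # brute-force oracle: a 4-point chiral configuration
        t = CaTrace([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [3.8, 3.8, 3.8]])
        assert kabsch_superpose(mirror_trace(t), t).rmsd > 0.1

    def test_rmsd_invariant_under_model_prerotation(self, rng):
        t = random_chain(rng, 10)
        m = random_chain(rng, 10)
        r0 = kabsch_superpose(m, t).rmsd
        R = Rotation.from_rotvec([0.2, 0.9, -1.4])
        r1 = kabsch_superpose(CaTrace(R.apply(m.coords)), t).rmsd
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_too_few_points(self, rng):
        t = random_chain(rng, 8)
        with pytest.raises(InsufficientPointsError):
            kabsch_superpose(t, t, subset=[0, 1])


class TestPairwiseDistances:
    def test_two_points(self):
        t = CaTrace([[0, 0, 0], [3.8, 0, 0]])
        assert np.allclose(pairwise_distances(t), [[0, 3.8], [3.8, 0]])

    def test_symmetry_and_diagonal(self, rng):
        d = pairwise_distances(random_chain(rng, 12))
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_near_collinear_limit(self):
        t = internal_to_cartesian(
            InternalCoords([3.8, 3.8], [179.9999], [])
        )
        assert pairwise_distances(t)[0, 2] == pytest.approx(7.6, abs=1e-3)


class TestTraceValidation:
    def test_too_short(self):
        with pytest.raises(ChainTooShortError):
            CaTrace([[0.0, 0.0, 0.0]])

    def test_non_finite(self):
        from dgfold.exceptions import ShapeError

        with pytest.raises(ShapeError):
            CaTrace([[0, 0, 0], [np.nan, 0, 0]])
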