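"""GNM/ANM construction, decomposition, fluctuations and overlaps."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from enmpcn import elastic, fixtures, structures
from enmpcn.elastic import (
    DegenerateStructureError,
    ElasticParams,
    build_hessian,
    build_kirchhoff,
    cross_correlation,
    decompose,
    deformation_overlaps,
    hinge_sites,
    hotspots,
    matched_mode_sets,
    mode_overlap,
    mode_shape,
    overlap_matrix,
    square_fluctuations,
)

from helpers import random_structure


def two_residue_structure(distance):
    s = fixtures.linear_chain(2, spacing=distance)
    return s


class TestKirchhoff:
    def test_single_spring(self):
        k = build_kirchhoff(two_residue_structure(3.8))
        np.testing.assert_array_equal(k.matrix, [[1, -1], [-1, 1]])

    def test_beyond_cutoff_gives_zero_matrix(self):
        k = build_kirchhoff(two_residue_structure(8.0))
        np.testing.assert_array_equal(k.matrix, np.zeros((2, 2)))
        with pytest.raises(DegenerateStructureError):
            decompose(k)

    def test_path_graph_laplacian(self, chain5):
        k = build_kirchhoff(chain5)
        dist = np.abs(np.subtract.outer(np.arange(5), np.arange(5))) * 3.8
        expected = -(
            (dist <= 7.0) & (dist > 0)
        ).astype(float)
        np.fill_diagonal(expected, -expected.sum(axis=1))
        np.testing.assert_array_equal(k.matrix, expected)
        assert np.diag(k.matrix).tolist() == [1, 2, 2, 2, 1]

    def test_row_sums_zero_exactly(self, tetramer):
        k = build_kirchhoff(tetramer)
        assert np.abs(k.matrix.sum(axis=1)).max() == 0


class TestDecompose:
    def test_three_node_path_eigenvalues(self, chain3):
        modes = decompose(build_kirchhoff(chain3))
        np.testing.assert_allclose(modes.eigenvalues, [1.0, 3.0], atol=1e-12)
        assert modes.n_zero == 1

    def test_zero_mode_is_constant_vector(self, tetramer):
        modes = decompose(build_kirchhoff(tetramer))
        # the discarded null space is the constant vector: all kept
        # eigenvectors must be orthogonal to it
        ones = np.ones(len(tetramer)) / np.sqrt(len(tetramer))
        assert np.abs(modes.eigenvectors.T @ ones).max() < 1e-8

    def test_orthonormal(self, tetramer):
        modes = decompose(build_kirchhoff(tetramer))
        gram = modes.eigenvectors.T @ modes.eigenvectors
        np.testing.assert_allclose(gram, np.eye(modes.n_modes), atol=1e-8)

    def test_anm_six_zero_modes(self):
        s = fixtures.helix_chain(4)
        modes = decompose(build_hessian(s))
        assert modes.n_zero == 6

    def test_collinear_anm_degenerate(self, chain5):
        with pytest.raises(DegenerateStructureError):
            decompose(build_hessian(chain5))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=4, max_value=8), st.integers(min_value=0, max_value=1000))
    def test_eigenvalues_match_independent_solver(self, n, seed):
        """Dense symmetric solver vs general nonsymmetric QR on tiny toys."""
        rng = np.random.default_rng(seed)
        s = random_structure(rng, n)
        k = build_kirchhoff(s)
        ours = np.concatenate([[0.0] * 1, decompose(k).eigenvalues])
        other = np.sort(scipy.linalg.eig(k.matrix)[0].real)
        np.testing.assert_allclose(ours, other, atol=1e-9)


class TestSquareFluctuations:
    def test_three_node_path_values(self, chain3):
        modes = decompose(build_kirchhoff(chain3))
        np.testing.assert_allclose(
            square_fluctuations(modes), [5 / 9, 2 / 9, 5 / 9], atol=1e-12
        )

    def test_equals_pseudoinverse_diagonal(self, tetramer):
        k = build_kirchhoff(tetramer)
        modes = decompose(k)
        np.testing.assert_allclose(
            square_fluctuations(modes),
            np.diag(np.linalg.pinv(k.matrix, hermitian=True)),
            atol=1e-10,
        )

    def test_mirror_symmetry(self, tetramer):
        modes = decompose(build_kirchhoff(tetramer))
        msf = square_fluctuations(modes)
        sl = tetramer.chain_slices()
        np.testing.assert_allclose(msf[sl["A"]], msf[sl["C"]], atol=1e-9)
        np.testing.assert_allclose(msf[sl["B"]], msf[sl["D"]], atol=1e-9)

    def test_monotone_in_mode_subset(self, tetramer):
        modes = decompose(build_kirchhoff(tetramer))
        prev = np.zeros(len(tetramer))
        for m in (1, 3, 10, modes.n_modes):
            cur = square_fluctuations(modes, mode_indices=range(1, m + 1))
            assert np.all(cur >= prev - 1e-14)
            prev = cur

    def test_empty_subset_error(self, chain3):
        modes = decompose(build_kirchhoff(chain3))
        with pytest.raises(ValueError):
            square_fluctuations(modes, mode_indices=[])

    def test_rigid_motion_invariance(self, tetramer):
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=3).as_matrix()
        moved = tetramer.transformed(rot, np.array([4.0, 4.0, -9.0]))
        a = square_fluctuations(decompose(build_kirchhoff(tetramer)))
        b = square_fluctuations(decompose(build_kirchhoff(moved)))
        np.testing.assert_allclose(a, b, atol=1e-10)
        ha = square_fluctuations(decompose(build_hessian(tetramer)))
        hb = square_fluctuations(decompose(build_hessian(moved)))
        np.testing.assert_allclose(ha, hb, atol=1e-8)


class TestCrossCorrelation:
    def test_diagonal_is_one(self, tetramer):
        corr = cross_correlation(decompose(build_kirchhoff(tetramer)))
        np.testing.assert_array_equal(np.diag(corr), np.ones(len(tetramer)))

    def test_single_mode_path_anticorrelation(self, chain3):
        modes = decompose(build_kirchhoff(chain3))
        corr = cross_correlation(modes, mode_indices=[1])
        assert corr[0, 2] == pytest.approx(-1.0)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.integers(min_value=4, max_value=10), st.integers(min_value=0, max_value=500))
    def test_bounded(self, n, seed):
        rng = np.random.default_rng(seed)
        modes = decompose(build_kirchhoff(random_structure(rng, n)))
        corr = cross_correlation(modes)
        assert np.nanmax(np.abs(corr)) <= 1 + 1e-12

    def test_slow_mode_splits_tetramer_into_dimers(self, tetramer):
        corr = cross_correlation(decompose(build_kirchhoff(tetramer)), mode_indices=[1])
        sl = tetramer.chain_slices()
        ab = list(range(sl["A"].start, sl["B"].stop))
        cd = list(range(sl["C"].start, sl["D"].stop))
        assert np.sign(corr[np.ix_(ab, ab)]).min() == 1  # within-dimer correlated
        assert np.sign(corr[np.ix_(ab, cd)]).max() == -1  # across dimers anticorrelated


class TestHinges:
    def test_strictly_positive_shape_has_none(self, chain5):
        assert hinge_sites(chain5, np.ones(5)) == []

    def test_path_sign_change(self, chain3):
        modes = decompose(build_kirchhoff(chain3))
        shape = mode_shape(modes, 1)
        assert hinge_sites(chain3, shape) == [1]

    def test_tetramer_hinges_between_dimers(self, tetramer):
        modes = decompose(build_kirchhoff(tetramer))
        hinges = hinge_sites(tetramer, mode_shape(modes, 1))
        # the slow mode separates the two dimers, so its near-zero band is
        # symmetric under the dimer swap
        n = len(tetramer)
        sl = tetramer.chain_slices()
        mapped = set()
        for i in hinges:
            if i < sl["C"].start:
                mapped.add(i + sl["C"].start)
            else:
                mapped.add(i - sl["C"].start)
        assert mapped == set(hinges)


class TestHessian:
    def test_two_nodes_along_x(self):
        s = two_residue_structure(5.0)
        h = build_hessian(s)
        evals = np.sort(scipy.linalg.eigvalsh(h.matrix))
        np.testing.assert_allclose(evals[:5], 0, atol=1e-12)
        assert evals[5] == pytest.approx(2.0)
        # eigenvector is the ±x relative displacement
        _, vecs = scipy.linalg.eigh(h.matrix)
        v = vecs[:, -1].reshape(2, 3)
        np.testing.assert_allclose(np.abs(v[:, 0]), [np.sqrt(0.5)] * 2, atol=1e-12)
        np.testing.assert_allclose(v[:, 1:], 0, atol=1e-12)

    def test_pair_along_y_block_structure(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 6.0, 0.0]])
        s = fixtures.linear_chain(2)
        s = structures.CoarseStructure(
            residues=list(s.residues), coords=coords,
            atom_names=[["CA"], ["CA"]], atom_coords=[coords[:1], coords[1:]],
        )
        h = build_hessian(s).matrix
        block = h[0:3, 3:6]
        assert block[0, 0] == 0 and block[2, 2] == 0
        assert block[1, 1] == pytest.approx(-1.0)

    def test_symmetric_and_annihilates_rigid_motions(self, tetramer):
        h = build_hessian(tetramer).matrix
        np.testing.assert_allclose(h, h.T, atol=1e-12)
        n = len(tetramer)
        for axis in range(3):
            t = np.zeros(3 * n)
            t[axis::3] = 1.0
            assert np.abs(h @ t).max() < 1e-8
        # infinitesimal rotations about each axis, evaluated at equilibrium
        centered = tetramer.coords - tetramer.coords.mean(axis=0)
        for axis in range(3):
            omega = np.zeros(3)
            omega[axis] = 1.0
            rotfield = np.cross(omega, centered).ravel()
            assert np.abs(h @ rotfield).max() < 1e-6


class TestOverlaps:
    def test_self_overlap_is_one(self, tetramer):
        modes = decompose(build_kirchhoff(tetramer))
        assert mode_overlap(modes.mode(1), modes.mode(1)) == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mode_overlap(np.ones(3), np.ones(4))

    def test_parseval_over_complete_basis(self, two_state_pair):
        # GNM null spaces of the two conformations coincide (the constant
        # vector), so the cross-conformation overlap rows are exactly complete
        s1, s2 = two_state_pair
        m1, m2, _ = matched_mode_sets(s1, s2, "GNM")
        full = overlap_matrix(m1, m2, m1.n_modes)
        np.testing.assert_allclose((full**2).sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose((full**2).sum(axis=0), 1.0, atol=1e-6)
        partial = overlap_matrix(m1, m2, 10)
        assert np.all((partial**2).sum(axis=1) <= 1 + 1e-9)

    def test_anm_cross_conformation_rows_bounded(self, two_state_pair):
        # ANM rigid-rotation null spaces differ between conformations, so
        # the row sums are bounded by 1 and deficient only by O(angle²)
        s1, s2 = two_state_pair
        m1, m2, _ = matched_mode_sets(s1, s2, "ANM")
        rows = (overlap_matrix(m1, m2, m1.n_modes) ** 2).sum(axis=1)
        assert np.all(rows <= 1 + 1e-9)
        assert rows.min() > 0.999

    def test_deformation_equal_to_single_mode(self, tetramer):
        modes = decompose(build_hessian(tetramer))
        result = deformation_overlaps(modes, modes.mode(4))
        assert result.overlaps[3] == pytest.approx(1.0)
        assert result.best_mode == 4
        others = np.delete(result.overlaps, 3)
        np.testing.assert_allclose(others, 0, atol=1e-9)

    def test_cumulative_reaches_one(self, two_state_pair):
        s1, s2 = two_state_pair
        modes = decompose(build_hessian(s1))
        delta = structures.superpose(s2, s1)
        result = deformation_overlaps(modes, delta)
        assert np.all(np.diff(result.cumulative) >= -1e-12)
        assert result.cumulative[-1] == pytest.approx(1.0, abs=1e-6)
        # the per-mode projections match a brute-force projection
        dr = delta.delta_r / delta.magnitude
        brute = np.abs(modes.eigenvectors.T @ dr)
        np.testing.assert_allclose(result.overlaps, brute, atol=1e-12)

    def test_zero_deformation_error(self, tetramer):
        modes = decompose(build_hessian(tetramer))
        with pytest.raises(ValueError):
            deformation_overlaps(modes, np.zeros(3 * len(tetramer)))


class TestHotspots:
    def test_ring_is_flat(self):
        # odd ring: the two highest modes are a complete degenerate pair, so
        # their combined profile shares the full rotational symmetry
        ring = fixtures.ring_chain(13)
        modes = decompose(build_kirchhoff(ring))
        spots, profile = hotspots(ring, modes)
        assert spots == []
        assert np.ptp(profile) < 1e-9

    def test_densest_node_dominates_high_frequency(self):
        # star geometry: hub at the origin, six octahedral satellites at
        # 6 Å (mutually 8.5 Å apart, beyond the cutoff) — the hub is the
        # unique maximal-contact-density node
        sat = 6.0 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        coords = np.vstack([sat[:3], np.zeros(3), sat[3:]])
        s = fixtures.linear_chain(7)
        star = structures.CoarseStructure(
            residues=list(s.residues), coords=coords,
            atom_names=[["CA"]] * 7, atom_coords=[coords[i : i + 1] for i in range(7)],
        )
        k = build_kirchhoff(star)
        assert np.argmax(np.diag(k.matrix)) == 3
        modes = decompose(k)
        profile = square_fluctuations(modes, mode_indices=[modes.n_modes])
        # independent eigendecomposition oracle
        evals, evecs = np.linalg.eigh(k.matrix)
        oracle = evecs[:, -1] ** 2 / evals[-1]
        np.testing.assert_allclose(profile, oracle, atol=1e-10)
        assert np.argmax(profile) == 3
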