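"""Source grids, conducting-sphere lead fields and the LCMV beamformer."""

import numpy as np
import pytest

from telemeg import source, synth
from telemeg.source import (
    dipole_field_sphere,
    lcmv_scalar,
    lcmv_weights,
    leadfield_sphere,
    localize_envelope_power,
    make_grid,
    reduce_rank,
    reduce_rank_leadfield,
    regularized_inverse,
)

MU0_4PI = 1e-7


@pytest.fixture(scope="module")
def grid_and_leadfield(array64):
    # centre offset half a step so the lattice avoids the sphere origin,
    # where the forward model is singular
    grid = make_grid((0.0025, 0.0025, 0.0025), radius=0.05, spacing=0.005)
    L = reduce_rank_leadfield(leadfield_sphere(grid, array64))
    return grid, L


class TestMakeGrid:
    def test_small_sphere_lattice_count(self):
        # brute-force count of lattice points with |p| <= 1 cm at 5 mm pitch
        grid = make_grid((0, 0, 0), radius=0.01, spacing=0.005)
        assert grid.n_sources == 33

    def test_all_points_inside(self):
        grid = make_grid((0.01, 0.0, 0.02), radius=0.03, spacing=0.007)
        d = np.linalg.norm(grid.points - [0.01, 0.0, 0.02], axis=1)
        assert (d <= 0.03 + 1e-12).all()

    def test_degenerate_spacing_single_point(self):
        grid = make_grid((0, 0, 0), radius=0.004, spacing=0.01)
        assert grid.n_sources == 1

    def test_min_spacing_matches(self):
        grid = make_grid((0, 0, 0), radius=0.02, spacing=0.005)
        from scipy.spatial.distance import pdist
        assert pdist(grid.points).min() == pytest.approx(0.005, abs=1e-9)

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError, match="empty"):
            make_grid((0, 0, 0), radius=0.03, spacing=0.005,
                      mask_fn=lambda p: np.zeros(len(p), dtype=bool))


class TestDipoleFieldSphere:
    def test_radial_dipole_silent(self, array64):
        r0 = np.array([0.01, 0.03, 0.04])
        B = dipole_field_sphere(r0, 2e-8 * r0 / np.linalg.norm(r0),
                                array64.positions)
        assert np.abs(B).max() <= 1e-12

    def test_linearity_in_moment(self, array64):
        r0 = np.array([0.0, 0.03, 0.04])
        Q = np.array([1e-8, 3e-9, 0.0])
        B1 = dipole_field_sphere(r0, Q, array64.positions)
        B2 = dipole_field_sphere(r0, 2 * Q, array64.positions)
        np.testing.assert_allclose(B2, 2 * B1, rtol=1e-12)

    def test_radial_component_equals_free_space_dipole(self, array64):
        """Independent oracle: outside a spherically symmetric conductor the
        radial field component is exactly that of the primary (free-space)
        current dipole — volume currents contribute no radial field."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            r0 = rng.uniform(-0.04, 0.04, size=3)
            Q = 1e-8 * rng.normal(size=3)
            B = dipole_field_sphere(r0, Q, array64.positions)
            rhat = array64.positions / np.linalg.norm(
                array64.positions, axis=1, keepdims=True)
            Br = np.einsum("ij,ij->i", B, rhat)
            a = array64.positions - r0
            B_free = MU0_4PI * np.cross(Q, a) / \
                np.linalg.norm(a, axis=1, keepdims=True) ** 3
            Br_free = np.einsum("ij,ij->i", B_free, rhat)
            np.testing.assert_allclose(Br, Br_free, rtol=1e-10,
                                       atol=1e-16 * np.abs(Br_free).max())

    def test_origin_and_coincident_errors(self, array64):
        with pytest.raises(ValueError, match="origin"):
            dipole_field_sphere(np.zeros(3), np.ones(3), array64.positions)
        with pytest.raises(ValueError, match="coincident"):
            dipole_field_sphere(array64.positions[0], np.ones(3),
                                array64.positions)


class TestReduceRank:
    def test_rank2_exact_reconstruction(self):
        rng = np.random.default_rng(1)
        L = rng.normal(size=(20, 2)) @ rng.normal(size=(2, 3))
        L2, basis = reduce_rank(L)
        recon = L2 @ basis.T
        np.testing.assert_allclose(recon, L, atol=1e-12)

    def test_sphere_leadfield_third_sv_tiny(self, array64):
        grid = make_grid((0.0, 0.01, 0.02), radius=0.004, spacing=0.004)
        L = leadfield_sphere(grid, array64)
        s = np.linalg.svd(L.matrix[0], compute_uv=False)
        assert s[2] < 1e-10 * s[0]           # the silent radial direction

    def test_retained_columns_orthogonal(self):
        rng = np.random.default_rng(2)
        L2, basis = reduce_rank(rng.normal(size=(30, 3)))
        assert abs(L2[:, 0] @ L2[:, 1]) < 1e-9 * np.linalg.norm(L2[:, 0]) \
            * np.linalg.norm(L2[:, 1])
        np.testing.assert_allclose(basis.T @ basis, np.eye(2), atol=1e-12)

    def test_rank1_errors(self):
        L = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="rank"):
            reduce_rank(L)


class TestRegularizedInverse:
    def test_identity_inverse(self):
        Ci, w = regularized_inverse(np.eye(5), discard=0)
        np.testing.assert_allclose(Ci, np.eye(5), atol=1e-12)

    def test_projected_covariance_pseudo_inverse(self, array64):
        from telemeg.preproc import hfc_basis
        rng = np.random.default_rng(3)
        P = hfc_basis(array64).projector
        data = P @ rng.standard_normal((64, 5000))
        cov = np.cov(data)
        Ci, w = regularized_inverse(cov, discard=8)
        assert (w[-8:] < 1e-9 * w[0]).all()     # 8 near-zero eigenvalues
        v = P @ rng.standard_normal(64)         # any vector in retained span
        np.testing.assert_allclose(cov @ Ci @ v, v, atol=1e-6 * np.abs(v).max())

    def test_matches_numpy_pinv_on_rank_deficient(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            A = rng.normal(size=(12, 7))
            cov = A @ A.T                        # rank 7
            Ci, _ = regularized_inverse(cov, discard=5)
            np.testing.assert_allclose(Ci, np.linalg.pinv(cov, rcond=1e-10),
                                       atol=1e-8 * np.abs(Ci).max())

    def test_asymmetric_input_rejected(self):
        M = np.eye(4)
        M[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            regularized_inverse(M, discard=0)


class TestLcmv:
    def test_unit_gain_everywhere(self, array64, grid_and_leadfield):
        grid, L = grid_and_leadfield
        rng = np.random.default_rng(5)
        data = 1e-13 * rng.standard_normal((64, 4000))
        W = lcmv_weights(np.cov(data), L, discard=0)
        Ci, _ = regularized_inverse(np.cov(data), 0)
        for s in range(0, grid.n_sources, 197):
            w, ori = W.weights[s], W.orientations[s]
            l = L.matrix[s] @ (L.ori_basis[s].T @ ori)
            assert w @ l == pytest.approx(1.0, abs=1e-6)

    def test_orientation_recovery_high_snr(self, array64, grid_and_leadfield):
        grid, L = grid_and_leadfield
        rng = np.random.default_rng(6)
        gi = grid.n_sources // 3
        u_true = np.array([0.8, -0.6])
        l_true = L.matrix[gi] @ u_true
        data = np.outer(l_true, rng.standard_normal(6000))
        data += 1e-4 * np.abs(l_true).max() * rng.standard_normal(data.shape)
        Ci, _ = regularized_inverse(np.cov(data), 0)
        w, ori = lcmv_scalar(Ci, L.matrix[gi], L.ori_basis[gi])
        ori_true = L.ori_basis[gi] @ u_true
        ori_true /= np.linalg.norm(ori_true)
        angle = np.degrees(np.arccos(min(1.0, abs(ori @ ori_true))))
        assert angle < 5.0

    def test_white_noise_map_flat_after_depth_norm(self, array64,
                                                   grid_and_leadfield):
        grid, L = grid_and_leadfield
        rng = np.random.default_rng(7)
        data = 1e-13 * rng.standard_normal((64, 20000))
        W = lcmv_weights(np.cov(data), L, discard=0)
        var = localize_envelope_power(data, W, depth_normalize=True)
        assert var.std() / var.mean() < 0.15

    def test_planted_source_localised(self, array64, grid_and_leadfield):
        grid, L = grid_and_leadfield
        rng = np.random.default_rng(8)
        gi = int(np.argmin(np.linalg.norm(
            grid.points - [0.0, 0.025, 0.0325], axis=1)))
        l_true = L.matrix[gi] @ np.array([1.0, 0.3])
        s = rng.standard_normal(8000)
        data = np.outer(l_true, s)
        data += 0.3 * np.linalg.norm(l_true) / np.sqrt(64) \
            * rng.standard_normal(data.shape)
        W = lcmv_weights(np.cov(data), L, discard=0)
        var = localize_envelope_power(data, W, depth_normalize=True)
        err = np.linalg.norm(grid.points[var.argmax()] - grid.points[gi])
        assert err <= grid.spacing + 1e-12

    def test_two_sources_two_maxima(self, array64, grid_and_leadfield):
        grid, L = grid_and_leadfield
        rng = np.random.default_rng(9)
        g1 = int(np.argmin(np.linalg.norm(grid.points - [0.0, 0.03, 0.025],
                                          axis=1)))
        g2 = int(np.argmin(np.linalg.norm(grid.points - [0.0, -0.03, 0.025],
                                          axis=1)))
        l1 = L.matrix[g1] @ np.array([1.0, 0.0])
        l2 = L.matrix[g2] @ np.array([0.5, 0.8])
        data = np.outer(l1, rng.standard_normal(8000)) \
            + np.outer(l2 * np.linalg.norm(l1) / np.linalg.norm(l2),
                       rng.standard_normal(8000))
        data += 0.2 * np.linalg.norm(l1) / np.sqrt(64) \
            * rng.standard_normal(data.shape)
        W = lcmv_weights(np.cov(data), L, discard=0)
        var = localize_envelope_power(data, W, depth_normalize=True)
        for g in (g1, g2):
            near = np.linalg.norm(grid.points - grid.points[g],
                                  axis=1) <= grid.spacing + 1e-12
            assert var[near].max() >= 0.5 * var.max()

    def test_zero_data_zero_map(self, array64, grid_and_leadfield):
        grid, L = grid_and_leadfield
        rng = np.random.default_rng(10)
        cov = np.cov(1e-13 * rng.standard_normal((64, 2000)))
        W = lcmv_weights(cov, L, discard=0)
        var = localize_envelope_power(np.zeros((64, 100)), W)
        np.testing.assert_array_equal(var, 0.0)

    def test_scale_invariance_of_unit_gain_outputs(self, array64,
                                                   grid_and_leadfield):
        """Rescaling the data rescales weights inversely; the reconstructed
        unit-gain source time course of the planted source is unchanged."""
        grid, L = grid_and_leadfield
        rng = np.random.default_rng(11)
        gi = grid.n_sources // 2
        l = L.matrix[gi] @ np.array([1.0, 0.5])
        data = np.outer(l, rng.standard_normal(3000))
        data += 0.1 * np.abs(l).max() * rng.standard_normal(data.shape)
        W1 = lcmv_weights(np.cov(data), L, discard=0)
        W2 = lcmv_weights(np.cov(7.0 * data), L, discard=0)
        s1 = W1.weights[gi] @ data
        s2 = W2.weights[gi] @ (7.0 * data)
        np.testing.assert_allclose(s2, 7.0 * s1, rtol=1e-6)


class TestCompensatedBeamforming:
    def test_localisation_consistent_with_and_without_hfc(self, array64):
        """Projected data + compensated lead fields find the same peak as
        unprojected data + raw lead fields."""
        from telemeg.preproc import apply_hfc, MEGRecording
        from telemeg.source import compensate
        rng = np.random.default_rng(12)
        grid = make_grid((0.0025, 0.0025, 0.0025), radius=0.045, spacing=0.006)
        L = reduce_rank_leadfield(leadfield_sphere(grid, array64))
        gi = int(np.argmin(np.linalg.norm(grid.points - [0.0, 0.02, 0.03],
                                          axis=1)))
        l = L.matrix[gi] @ np.array([1.0, 0.2])
        data = np.outer(l, rng.standard_normal(5000))
        data += 0.2 * np.linalg.norm(l) / np.sqrt(64) \
            * rng.standard_normal(data.shape)

        W_raw = lcmv_weights(np.cov(data), L, discard=0)
        peak_raw = localize_envelope_power(data, W_raw,
                                           depth_normalize=True).argmax()

        rec, op = apply_hfc(MEGRecording(data, 1000.0, array64))
        Lc = compensate(L, op)
        W_c = lcmv_weights(np.cov(rec.data), Lc, discard=8)
        peak_c = localize_envelope_power(rec.data, W_c,
                                         depth_normalize=True).argmax()
        d = np.linalg.norm(grid.points[peak_raw] - grid.points[peak_c])
        assert d <= grid.spacing + 1e-12
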