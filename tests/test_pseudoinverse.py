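"""Generalized-inverse iteration: spectral bound, convergence, contraction."""

import numpy as np
import pytest

from iterfbp.core import parallel_geometry
from iterfbp.phantoms import make_disk_phantom
from iterfbp.projector import build_system_matrix, project
from iterfbp.pseudoinverse import (
    pseudoinverse_init,
    pseudoinverse_solve,
    pseudoinverse_step,
    select_theta,
    theta_bound,
)

from conftest import near_optimal_theta, toy_system


def _identity_system(scale=1.0, n=4):
    import scipy.sparse as sp

    from iterfbp.core import Geometry, SystemMatrix

    geom = Geometry(angles=np.array([0.0]), num_bins=n, bin_spacing=1000.0)
    return SystemMatrix(
        geometry=geom, height=1, width=n, pixel_size=1.0,
        entries=sp.csr_matrix(scale * np.eye(n)),
    )


class TestThetaBound:
    def test_identity_spectrum_gives_bound_two(self):
        assert theta_bound(_identity_system()) == pytest.approx(2.0, rel=1e-8)

    def test_scaling_by_two_quarters_the_bound(self):
        assert theta_bound(_identity_system(scale=2.0)) == pytest.approx(0.5, rel=1e-8)

    def test_power_iteration_matches_dense_eigendecomposition(self):
        E = toy_system((6, 9), seed=11)
        dense = E.toarray()
        lam1 = np.linalg.eigvalsh(dense @ dense.T).max()
        assert theta_bound(E) == pytest.approx(2.0 / lam1, rel=1e-6)

    def test_zero_matrix_rejected(self):
        import scipy.sparse as sp

        from iterfbp.core import Geometry, SystemMatrix

        geom = Geometry(angles=np.array([0.0]), num_bins=2, bin_spacing=1000.0)
        E = SystemMatrix(geometry=geom, height=1, width=2, pixel_size=1.0,
                         entries=sp.csr_matrix((2, 2)))
        with pytest.raises(ValueError):
            theta_bound(E)


class TestSelectTheta:
    def test_underdetermined_image_with_small_spectrum_gives_one(self):
        """hw < YX and lam_1(E E^T) <= 2 selects the nominal theta = 1."""
        import scipy.sparse as sp

        from iterfbp.core import Geometry, SystemMatrix

        geom = Geometry(angles=np.array([0.0, 0.5, 1.0, 1.5]), num_bins=3,
                        bin_spacing=1000.0)
        rng = np.random.default_rng(0)
        E = SystemMatrix(geometry=geom, height=2, width=2, pixel_size=1.0,
                         entries=sp.csr_matrix(0.2 * np.abs(rng.standard_normal((12, 4)))))
        dense = E.toarray()
        assert np.linalg.eigvalsh(dense @ dense.T).max() <= 2.0
        assert select_theta(2, 2, 4, 3, E) == 1.0

    def test_overdetermined_image_uses_exponential_rule(self):
        # hw == YX == 4 with an identity-like E whose cap exceeds 0.5
        E = _identity_system(scale=0.5, n=4)  # bound = 2/0.25 = 8
        assert select_theta(1, 4, 1, 4, E) == pytest.approx(0.5)

    @pytest.mark.parametrize("shape,seed", [((4, 6), 1), ((6, 4), 2), ((8, 8), 3)])
    def test_output_strictly_inside_spectral_interval(self, shape, seed):
        E = toy_system(shape, seed)
        theta = select_theta(1, shape[1], 1, shape[0], E)
        assert 0.0 < theta < theta_bound(E)


class TestInitAndStep:
    def test_identity_initialization_has_zero_residual(self):
        state = pseudoinverse_init(_identity_system(), theta=1.0)
        np.testing.assert_allclose(state.P, np.eye(4))
        assert state.residual_norm == pytest.approx(0.0, abs=1e-12)

    def test_initial_matrix_is_theta_times_transpose(self):
        E = toy_system((4, 6), seed=5)
        theta = 0.5 * theta_bound(E)
        state = pseudoinverse_init(E, theta)
        np.testing.assert_array_equal(state.P, theta * E.toarray().T)

    def test_initial_residual_matches_dense_oracle(self):
        """||Pi_range(E) - theta E E^T|| against an explicit SVD projector."""
        E = toy_system((4, 6), seed=8)
        dense = E.toarray()
        lam1 = np.linalg.eigvalsh(dense @ dense.T).max()
        theta = 1.0 / lam1
        state = pseudoinverse_init(E, theta)
        u, s, _ = np.linalg.svd(dense)
        projector = u @ u.T  # full row rank: projector is identity on R^4
        oracle = np.linalg.norm(projector - theta * dense @ dense.T, 2)
        assert state.residual_norm == pytest.approx(oracle, abs=1e-8)

    def test_theta_outside_open_interval_rejected(self):
        E = toy_system((4, 6), seed=5)
        bound = theta_bound(E)
        for bad in (0.0, -0.1, bound, 1.5 * bound):
            with pytest.raises(ValueError):
                pseudoinverse_init(E, bad)

    def test_identity_is_a_fixed_point(self):
        E = _identity_system()
        state = pseudoinverse_init(E, theta=1.0)
        P0 = state.P.copy()
        for _ in range(3):
            state = pseudoinverse_step(state, E, P0)
            np.testing.assert_allclose(state.P, np.eye(4), atol=1e-14)

    def test_orthogonal_operator_inverts_in_one_step(self):
        """For orthogonal E with theta=1, P0 E = I so P1 = E^T = E^-1."""
        import scipy.sparse as sp

        from iterfbp.core import Geometry, SystemMatrix

        # a permutation matrix is orthogonal with non-negative entries
        perm = np.eye(4)[[2, 0, 3, 1]]
        geom = Geometry(angles=np.array([0.0]), num_bins=4, bin_spacing=1000.0)
        E = SystemMatrix(geometry=geom, height=1, width=4, pixel_size=1.0,
                         entries=sp.csr_matrix(perm))
        state = pseudoinverse_init(E, theta=1.0)
        state = pseudoinverse_step(state, E, state.P.copy())
        np.testing.assert_allclose(state.P, perm.T, atol=1e-12)


class TestConvergence:
    @pytest.mark.parametrize(
        "shape,seed,dup", [((4, 6), 1, 0), ((6, 4), 2, 0), ((8, 8), 3, 3)]
    )
    def test_iteration_converges_to_moore_penrose_inverse(self, shape, seed, dup):
        """||P_K - E+||_F falls below 1e-6 within 500 steps (SVD oracle)."""
        E = toy_system(shape, seed, dup_rows=dup)
        theta = near_optimal_theta(E)
        assert 0.0 < theta < theta_bound(E)
        state = pseudoinverse_init(E, theta)
        P0 = state.P.copy()
        for _ in range(500):
            state = pseudoinverse_step(state, E, P0)
        pinv = np.linalg.pinv(E.toarray())
        assert np.linalg.norm(state.P - pinv) < 1e-6

    @pytest.mark.parametrize(
        "shape,seed,dup", [((4, 6), 1, 0), ((6, 4), 2, 0), ((8, 8), 3, 3)]
    )
    def test_residual_contracts_strictly_while_above_precision(self, shape, seed, dup):
        """With ||C_0|| < 1 the residual norms strictly decrease."""
        E = toy_system(shape, seed, dup_rows=dup)
        state = pseudoinverse_init(E, near_optimal_theta(E))
        assert state.residual_norm < 1.0
        P0 = state.P.copy()
        previous = state.residual_norm
        for _ in range(60):
            state = pseudoinverse_step(state, E, P0)
            if previous < 1e-12:
                break
            assert state.residual_norm < previous
            previous = state.residual_norm

    def test_out_of_bound_theta_diverges_detectably(self):
        E = toy_system((4, 6), seed=1)
        theta = 1.01 * theta_bound(E)
        state = pseudoinverse_init(E, theta, enforce_bound=False)
        initial = state.residual_norm
        P0 = state.P.copy()
        for _ in range(300):
            state = pseudoinverse_step(state, E, P0)
        assert state.residual_norm > 10 * max(initial, 1.0)


class TestSolve:
    def test_matches_dense_least_squares_on_a_real_system(self):
        """4x4 phantom, 8 angles x 6 bins, noiseless data."""
        geom = parallel_geometry(8, 4, 4, num_bins=6, bin_spacing=1.0)
        E = build_system_matrix(geom, 4, 4, 1.0)
        truth = make_disk_phantom(4, 4, 0.4, 0.8)
        U = project(truth, geom)
        with pytest.warns(RuntimeWarning):
            result = pseudoinverse_solve(E, U, phi=0.0, max_iters=3000)
        x_ls = np.linalg.lstsq(E.toarray(), U.flatten(), rcond=None)[0]
        rms = np.sqrt(np.mean((result.image.flatten() - x_ls) ** 2))
        assert rms < 1e-5

    def test_zero_sinogram_converges_immediately_to_zero(self):
        geom = parallel_geometry(8, 4, 4, num_bins=6, bin_spacing=1.0)
        E = build_system_matrix(geom, 4, 4, 1.0)
        from iterfbp.core import Sinogram

        result = pseudoinverse_solve(E, Sinogram(geom, np.zeros((8, 6))))
        assert np.array_equal(result.image.values, np.zeros((4, 4)))
        assert result.converged and result.iterations == 1

    def test_data_residual_never_grows_with_more_iterations(self):
        """Doubling the iteration cap cannot worsen ||E x - U|| (noiseless)."""
        geom = parallel_geometry(8, 4, 4, num_bins=6, bin_spacing=1.0)
        E = build_system_matrix(geom, 4, 4, 1.0)
        U = project(make_disk_phantom(4, 4, 0.4, 0.8), geom)
        residuals = []
        for cap in (50, 100, 200):
            with pytest.warns(RuntimeWarning):
                result = pseudoinverse_solve(E, U, phi=0.0, max_iters=cap)
            residuals.append(
                np.linalg.norm(E.entries @ result.image.flatten() - U.flatten())
            )
        assert residuals[0] >= residuals[1] >= residuals[2]

    def test_large_grid_rejected_for_dense_path(self):
        geom = parallel_geometry(60, 64, 64)
        E_small_ok = 64 * 64 > 1024  # the dense path contract
        assert E_small_ok
        with pytest.raises(ValueError, match="dense"):
            build_and_init(geom)


def build_and_init(geom):
    E = build_system_matrix(geom, 64, 64, 1.0)
    return pseudoinverse_init(E, 0.1)
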