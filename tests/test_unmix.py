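"""Pixel-wise LASSO unmixing: closed forms, oracles, and invariants."""

import numpy as np
import pytest

from srskit.simulate import HyperspectralStack, fingerprint_axis
from srskit.unmix import (
    UnmixConfig,
    crosstalk_score,
    lasso_objective,
    lasso_solve,
    lasso_solve_pixel,
    matrix_to_stack,
    stack_to_matrix,
    tune_beta,
    unmix_stack,
)


class TestStackToMatrix:
    def test_raster_order_convention(self, axis32):
        data = np.arange(2 * 2 * 32, dtype=np.float32).reshape(32, 2, 2)
        stack = HyperspectralStack(data=data, axis=axis32)
        D = stack_to_matrix(stack)
        assert D.shape == (4, 32)
        np.testing.assert_array_equal(D[0], data[:, 0, 0])
        np.testing.assert_array_equal(D[1], data[:, 0, 1])
        np.testing.assert_array_equal(D[2], data[:, 1, 0])
        np.testing.assert_array_equal(D[3], data[:, 1, 1])

    def test_roundtrip_identity(self, clean_stack):
        D = stack_to_matrix(clean_stack)
        back = matrix_to_stack(D, clean_stack)
        np.testing.assert_array_equal(back.data, clean_stack.data)

    def test_brute_force_index_oracle(self):
        axis = fingerprint_axis(5)
        rng = np.random.default_rng(0)
        data = rng.uniform(size=(5, 3, 4)).astype(np.float32)
        D = stack_to_matrix(HyperspectralStack(data=data, axis=axis))
        for y in range(3):
            for x in range(4):
                for lam in range(5):
                    assert D[y * 4 + x, lam] == data[lam, y, x]


class TestLassoSolvePixel:
    def test_beta_zero_single_unit_norm_component(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=20)
        s /= np.linalg.norm(s)
        d = rng.normal(size=20)
        c = lasso_solve_pixel(d, s[None, :], UnmixConfig(beta=0.0))
        assert c[0] == pytest.approx(float(d @ s), abs=1e-10)

    def test_orthonormal_design_soft_threshold_closed_form(self):
        rng = np.random.default_rng(2)
        S, _ = np.linalg.qr(rng.normal(size=(30, 3)))
        S = S.T  # 3 orthonormal rows
        d = rng.normal(size=30)
        beta = 0.2
        c = lasso_solve_pixel(d, S, UnmixConfig(beta=beta))
        rho = S @ d
        expected = np.sign(rho) * np.maximum(np.abs(rho) - beta, 0.0)
        np.testing.assert_allclose(c, expected, atol=1e-12)

    def test_beta_zero_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        S = rng.uniform(0, 1, (4, 25))
        d = rng.uniform(0, 1, 25)
        c = lasso_solve_pixel(d, S, UnmixConfig(beta=0.0, tolerance=1e-12, max_iter=20000))
        expected = np.linalg.solve(S @ S.T, S @ d)
        np.testing.assert_allclose(c, expected, atol=1e-8)

    def test_two_component_grid_search_oracle(self):
        # correlated spectra, beta = 0.1: the CD objective must match an
        # exhaustive grid search over [-2, 2]^2 at step 1e-3 within 1e-4
        rng = np.random.default_rng(4)
        t = np.linspace(0, 1, 40)
        S = np.stack([np.exp(-((t - 0.45) ** 2) / 0.02),
                      np.exp(-((t - 0.55) ** 2) / 0.02)])
        d = 0.8 * S[0] + 0.3 * S[1] + rng.normal(0, 0.05, 40)
        beta = 0.1
        c = lasso_solve_pixel(d, S, UnmixConfig(beta=beta, tolerance=1e-10))
        obj_cd = lasso_objective(c[None], d[None], S, beta)

        grid = np.arange(-2.0, 2.0 + 1e-9, 1e-3)
        b_vec = S @ d
        Q = S @ S.T
        c1 = grid[:, None]
        c2 = grid[None, :]
        obj = (
            0.5 * Q[0, 0] * c1**2
            + Q[0, 1] * c1 * c2
            + 0.5 * Q[1, 1] * c2**2
            - b_vec[0] * c1
            - b_vec[1] * c2
            + beta * (np.abs(c1) + np.abs(c2))
            + 0.5 * float(d @ d)
        )
        assert obj_cd <= obj.min() + 1e-4

    def test_nonnegative_mode_clamps_at_zero(self):
        rng = np.random.default_rng(5)
        S = rng.uniform(0, 1, (2, 15))
        d = -S[0]  # anti-correlated signal
        c = lasso_solve_pixel(d, S, UnmixConfig(beta=0.01, nonnegative=True))
        assert np.all(c >= 0)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            lasso_solve_pixel(np.array([1.0, np.nan]), np.ones((1, 2)), UnmixConfig())

    def test_matches_sklearn_lasso(self):
        # independent cross-check: sklearn minimizes 1/(2n)||d - Xw||^2 +
        # alpha ||w||_1, so alpha = beta / n maps onto our objective
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(6)
        S = rng.uniform(0, 1, (3, 50))
        d = rng.uniform(0, 1, 50)
        beta = 0.3
        ours = lasso_solve_pixel(d, S, UnmixConfig(beta=beta, tolerance=1e-12,
                                                   max_iter=50000))
        ref = sklearn.Lasso(alpha=beta / 50, fit_intercept=False, tol=1e-12,
                            max_iter=100000).fit(S.T, d)
        np.testing.assert_allclose(ours, ref.coef_, atol=1e-6)


class TestLassoInvariants:
    def test_objective_non_increasing_per_sweep(self):
        rng = np.random.default_rng(7)
        D = rng.uniform(0, 1, (20, 30))
        S = rng.uniform(0, 1, (4, 30))
        _, _, history = lasso_solve(D, S, UnmixConfig(beta=0.05), collect_objective=True)
        diffs = np.diff(history)
        assert np.all(diffs <= 1e-9)

    def test_support_shrinks_with_beta(self):
        rng = np.random.default_rng(8)
        S = rng.uniform(0, 1, (5, 40))
        d = rng.uniform(0, 1, 40)
        counts = []
        for beta in [0.0, 0.01, 0.05, 0.2, 1.0, 5.0]:
            c = lasso_solve_pixel(d, S, UnmixConfig(beta=beta, tolerance=1e-10))
            counts.append(int(np.sum(np.abs(c) > 1e-10)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestUnmixStack:
    def test_roundtrip_recovers_abundances(self, tiny_maps, library3, clean_stack):
        from srskit.simulate import render_clean_stack

        noiseless = render_clean_stack(tiny_maps, library3, baseline_amplitude=0.0)
        maps = unmix_stack(noiseless, library3,
                           UnmixConfig(beta=1e-6, tolerance=1e-10, max_iter=5000))
        np.testing.assert_allclose(maps.maps, tiny_maps, atol=1e-4)

    def test_all_zero_stack_gives_zero_maps(self, library3):
        stack = HyperspectralStack(
            data=np.zeros((32, 8, 8), np.float32), axis=library3.axis
        )
        maps = unmix_stack(stack, library3, UnmixConfig(beta=0.1))
        assert not maps.maps.any()
        assert not maps.residual_norm.any()

    def test_pixel_order_independence(self, clean_stack, library3):
        cfg = UnmixConfig(beta=1e-4, tolerance=1e-10)
        fwd = unmix_stack(clean_stack, library3, cfg)
        flipped = HyperspectralStack(
            data=clean_stack.data[:, ::-1, ::-1].copy(), axis=clean_stack.axis
        )
        rev = unmix_stack(flipped, library3, cfg)
        np.testing.assert_allclose(fwd.maps, rev.maps[::-1, ::-1], atol=1e-10)

    def test_axis_mismatch_rejected(self, library3):
        stack = HyperspectralStack(
            data=np.zeros((16, 4, 4), np.float32), axis=fingerprint_axis(16)
        )
        with pytest.raises(ValueError, match="axes"):
            unmix_stack(stack, library3, UnmixConfig())


class TestTuneBeta:
    @staticmethod
    def _separable_stack():
        # two chemicals with disjoint narrow bands -> perfectly separable
        axis = fingerprint_axis(64)
        from srskit.simulate import PeakSpec, ReferenceLibrary, synth_reference

        s1 = synth_reference([PeakSpec(1580.0, 8.0)], axis, 0.0)
        s2 = synth_reference([PeakSpec(1720.0, 8.0)], axis, 0.0)
        lib = ReferenceLibrary(("a", "b"), np.stack([s1, s2]), axis)
        ab = np.zeros((8, 8, 2))
        ab[:4, :, 0] = 1.0
        ab[4:, :, 1] = 1.0
        from srskit.simulate import render_clean_stack

        stack = render_clean_stack(ab, lib, 0.0)
        masks = {"a": ab[..., 0] > 0, "b": ab[..., 1] > 0}
        return stack, lib, masks

    def test_separable_spectra_pick_smallest_beta(self):
        stack, lib, masks = self._separable_stack()
        best = tune_beta(stack, lib, [1e-4, 1e-2, 1.0], masks)
        assert best == pytest.approx(1e-4)

    def test_matches_exhaustive_crosstalk_evaluation(self, library3, tiny_maps,
                                                     signal_mask, clean_stack):
        from srskit.simulate import corrupt, render_clean_stack

        noiseless = render_clean_stack(tiny_maps, library3, 0.0)
        noisy = corrupt(noiseless, 5.0, signal_mask, seed=3)
        masks = {
            "triglyceride": tiny_maps[..., 1] > 0.9,
            "cholesterol": tiny_maps[..., 2] > 0.8,
        }
        candidates = [1e-4, 1e-2, 0.1]
        best = tune_beta(noisy, library3, candidates, masks)
        scores = {
            b: crosstalk_score(
                unmix_stack(noisy, library3, UnmixConfig(beta=b)), masks
            )
            for b in candidates
        }
        assert best == min(sorted(candidates), key=lambda b: scores[b])

    def test_empty_mask_rejected(self, clean_stack, library3):
        with pytest.raises(ValueError):
            tune_beta(clean_stack, library3, [0.1],
                      {"bsa": np.zeros(clean_stack.shape[1:], bool)})
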