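"""Locally adaptive TV denoiser: local lambda, tiling, end-to-end behavior."""

import numpy as np
import pytest

from sinotv.adaptive import (
    LocalDenoiseConfig,
    counts_to_line_integrals,
    denoise_projection,
    denoise_stack,
    local_lambda,
    tiling_plan,
)
from sinotv.simulate import apply_poisson
from sinotv.tv import rof_denoise


class TestConfig:
    def test_defaults_follow_window_conventions(self):
        cfg = LocalDenoiseConfig(lam=0.1)
        assert (cfg.m, cfg.a) == (10, 4)
        assert cfg.h == 2 * cfg.m and cfg.h_prime == 2 * cfg.a

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LocalDenoiseConfig(lam=-0.1)
        with pytest.raises(ValueError):
            LocalDenoiseConfig(lam=0.1, m=2, a=4)


class TestLocalLambda:
    def test_constant_window(self):
        v = np.full((9, 9), 7.0)
        assert local_lambda(v, (4, 4), lam=0.2, a=2, h_prime=4.0) == pytest.approx(1.4)

    def test_all_zero_window_gives_zero(self):
        v = np.zeros((9, 9))
        assert local_lambda(v, (4, 4), lam=0.5, a=2, h_prime=4.0) == 0.0

    def test_three_by_three_hand_sum(self):
        """Direct nine-term W'-weighted average, W'(i,j)=exp(-(i^2+j^2)/4)."""
        v = np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]])
        di = np.arange(-1, 2)[:, None]
        dj = np.arange(-1, 2)[None, :]
        wp = np.exp(-(di**2 + dj**2) / 4.0)
        expected = (wp * v).sum() / wp.sum()
        got = local_lambda(v, (1, 1), lam=1.0, a=1, h_prime=2.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_border_window_clipped_and_renormalized(self):
        v = np.arange(25.0).reshape(5, 5)
        got = local_lambda(v, (0, 0), lam=1.0, a=2, h_prime=4.0)
        wp = np.exp(-(np.arange(3)[:, None] ** 2 + np.arange(3)[None, :] ** 2) / 16.0)
        expected = (wp * v[:3, :3]).sum() / wp.sum()
        assert got == pytest.approx(expected, rel=1e-12)


class TestTiling:
    @pytest.mark.parametrize("shape", [(27, 27), (128, 128), (50, 41), (9, 9)])
    def test_blocks_partition_image_exactly(self, shape):
        cover = np.zeros(shape, dtype=int)
        for t in tiling_plan(shape, m=10, a=4):
            cover[t.block] += 1
            wr, wc = t.window
            br, bc = t.block
            assert wr.start <= br.start and br.stop <= wr.stop
            assert wc.start <= bc.start and bc.stop <= wc.stop
        assert np.all(cover == 1)


class TestDenoiseProjection:
    def test_zero_lambda_identity(self, rng):
        v = rng.uniform(0, 10, size=(30, 30))
        np.testing.assert_array_equal(denoise_projection(v, LocalDenoiseConfig(lam=0.0)), v)

    def test_constant_image_unchanged(self):
        v = np.full((40, 40), 123.0)
        u = denoise_projection(v, LocalDenoiseConfig(lam=0.3))
        np.testing.assert_allclose(u, v, atol=1e-9)

    def test_all_zero_image_unchanged(self):
        v = np.zeros((30, 30))
        np.testing.assert_array_equal(denoise_projection(v, LocalDenoiseConfig(lam=0.3)), v)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            denoise_projection(np.full((10, 10), -1.0), LocalDenoiseConfig(lam=0.1))
        with pytest.raises(ValueError):
            denoise_projection(np.zeros((5, 5, 5)), LocalDenoiseConfig(lam=0.1, m=2, a=1))

    def test_reduces_rmse_on_poisson_counts(self):
        """Denoising noisy counts moves them closer to the noise-free truth."""
        li = np.fromfunction(lambda i, j: 2.0 * (np.sin(i / 15) ** 2) + j / 64, (48, 64))
        truth = 500.0 * np.exp(-li)
        noisy = apply_poisson(li, n0=500.0, seed=5).values.astype(float)
        u = denoise_projection(noisy, LocalDenoiseConfig(lam=0.1, m=6, a=2))
        assert np.sqrt(np.mean((u - truth) ** 2)) < np.sqrt(np.mean((noisy - truth) ** 2))

    def test_scale_equivariance(self, rng):
        """denoise(c*v; lam) = c*denoise(v; lam): lam' is signal-proportional."""
        v = rng.poisson(100.0, size=(36, 36)).astype(float)
        cfg = LocalDenoiseConfig(lam=0.15, m=6, a=2)
        u1 = denoise_projection(v, cfg)
        u2 = denoise_projection(3.7 * v, cfg)
        np.testing.assert_allclose(u2, 3.7 * u1, rtol=1e-6)

    def test_stronger_smoothing_on_brighter_plateau(self, rng):
        """Residual magnitude grows with signal level at fixed lam."""
        v = np.where(np.arange(60)[None, :] < 30, 100.0, 2000.0) * np.ones((45, 1))
        v = rng.poisson(v).astype(float)
        u = denoise_projection(v, LocalDenoiseConfig(lam=0.2))
        res = np.abs(u - v)
        assert res[:, 5:20].mean() < res[:, 40:55].mean()

    def test_noise_reduction_on_plateaus_across_lambda(self):
        truth = np.full((45, 45), 300.0)
        noisy = np.random.default_rng(2).poisson(truth).astype(float)
        for lam in (0.03, 0.1, 0.3):
            u = denoise_projection(noisy, LocalDenoiseConfig(lam=lam))
            assert (u - truth).std() < (noisy - truth).std()

    def test_block_mode_close_to_per_pixel_mode(self):
        """The (2a+1)-stride write-back approximates per-pixel denoising."""
        rng = np.random.default_rng(8)
        truth = np.full((24, 24), 200.0)
        noisy = rng.poisson(truth).astype(float)
        cfg = LocalDenoiseConfig(lam=0.1, m=6, a=2)
        ub = denoise_projection(noisy, cfg, mode="block")
        up = denoise_projection(noisy, cfg, mode="per_pixel")
        # both strongly denoised and close to each other relative to the noise
        assert np.abs(ub - up).mean() < 0.2 * (noisy - truth).std()

    def test_staircase_mitigation_on_ramp(self):
        """Local adaptive TV beats global ROF on a noisy linear ramp (best
        lambda over a 10-point grid for each method)."""
        ramp = np.tile(np.linspace(100.0, 1200.0, 64), (48, 1))
        noisy = np.random.default_rng(3).poisson(ramp).astype(float)

        def best_mse(denoiser, grid):
            return min(np.mean((denoiser(g) - ramp) ** 2) for g in grid)

        local = best_mse(
            lambda g: denoise_projection(noisy, LocalDenoiseConfig(lam=g)),
            np.logspace(-2, 0, 10),
        )
        glob = best_mse(
            lambda g: rof_denoise(noisy, g, max_iters=300, tol=1e-6)[0],
            np.logspace(0, 2.5, 10),
        )
        assert local <= glob


class TestStack:
    def test_single_view_stack_matches_projection(self, rng):
        v = rng.poisson(150.0, size=(1, 20, 20)).astype(float)
        cfg = LocalDenoiseConfig(lam=0.1, m=5, a=2)
        np.testing.assert_array_equal(
            denoise_stack(v, cfg)[0], denoise_projection(v[0], cfg)
        )

    def test_views_denoised_independently(self, rng):
        stack = rng.poisson(200.0, size=(4, 18, 18)).astype(float)
        cfg = LocalDenoiseConfig(lam=0.2, m=5, a=2)
        out = denoise_stack(stack, cfg)
        for k in range(4):
            np.testing.assert_array_equal(out[k], denoise_projection(stack[k], cfg))
        perm = [2, 0, 3, 1]
        np.testing.assert_array_equal(denoise_stack(stack[perm], cfg), out[perm])

    def test_ragged_stack_rejected(self):
        with pytest.raises(ValueError):
            denoise_stack([np.zeros((4, 4)), np.zeros((5, 5))], LocalDenoiseConfig(lam=0.1, m=2, a=1))


class TestCountsToLineIntegrals:
    def test_log_identities(self):
        assert counts_to_line_integrals(np.array([[500.0]]), 500.0)[0, 0] == 0.0
        got = counts_to_line_integrals(np.array([[500.0 / np.e]]), 500.0)[0, 0]
        assert got == pytest.approx(1.0, rel=1e-12)

    def test_zero_counts_clamped_to_half_photon(self):
        got = counts_to_line_integrals(np.array([[0.0]]), 500.0, eps_count=0.5)[0, 0]
        assert got == pytest.approx(np.log(1000.0), rel=1e-12)

    def test_counts_above_n0_clip_to_zero(self):
        assert counts_to_line_integrals(np.array([[700.0]]), 500.0)[0, 0] == 0.0
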