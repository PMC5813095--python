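"""Unit and property tests of the elastic NGF registration core."""
import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.ndimage import shift as ndshift

from elastimap import (
    RegistrationParams,
    assemble_elastic_operator,
    elastic_potential,
    estimate_epsilon,
    ngf_distance,
    normalized_gradient,
    register,
    similarity_force,
    solve_level,
    warp,
)
from elastimap.registration import _upsample_field


def smooth_random_image(rng, shape=(8, 8), sigma=1.0, scale=1.0):
    return gaussian_filter(rng.standard_normal(shape), sigma) * scale


# ---------------------------------------------------------------------------
# epsilon


class TestEstimateEpsilon:
    def test_constant_image_returns_positive_floor(self):
        eps = estimate_epsilon(np.full((16, 16), 7.0))
        assert eps > 0

    def test_scales_linearly_with_intensity(self, rng):
        img = smooth_random_image(rng, (16, 16))
        assert estimate_epsilon(2 * img) == pytest.approx(2 * estimate_epsilon(img))

    def test_step_edge_matches_brute_force_edge_mass(self):
        img = np.zeros((12, 12))
        img[:, 6:] = 1.0  # unit step edge
        gy, gx = np.gradient(img)
        mean_modulus = sum(
            np.hypot(gy[i, j], gx[i, j]) for i in range(12) for j in range(12)
        ) / img.size
        assert estimate_epsilon(img, 0.1) == pytest.approx(0.1 * mean_modulus)


# ---------------------------------------------------------------------------
# normalized gradient


class TestNormalizedGradient:
    def test_constant_image_gives_zero_vectors(self):
        n = normalized_gradient(np.full((8, 8), 3.0), epsilon=0.5)
        assert np.allclose(n, 0.0)

    def test_ramp_approaches_unit_vector_as_epsilon_vanishes(self):
        img = np.tile(np.arange(10.0), (10, 1))  # I(x, y) = x (column ramp)
        n = normalized_gradient(img, epsilon=1e-9)
        assert np.allclose(n[..., 1], 1.0, atol=1e-6)
        assert np.allclose(n[..., 0], 0.0, atol=1e-6)

    def test_ramp_with_epsilon_equal_gradient_has_norm_inv_sqrt2(self):
        g = 2.5
        img = g * np.tile(np.arange(9.0), (9, 1))
        n = normalized_gradient(img, epsilon=g)
        norms = np.hypot(n[..., 0], n[..., 1])
        assert np.allclose(norms, 1.0 / np.sqrt(2.0))

    def test_norms_strictly_below_one(self, rng):
        img = smooth_random_image(rng, (12, 12))
        n = normalized_gradient(img, epsilon=estimate_epsilon(img))
        assert np.all(np.hypot(n[..., 0], n[..., 1]) < 1.0)


# ---------------------------------------------------------------------------
# NGF distance


class TestNgfDistance:
    def test_two_constant_images_give_half_domain_measure(self):
        r = np.full((9, 7), 4.0)
        t = np.full((9, 7), -2.0)
        d = ngf_distance(r, t)
        # brute-force oracle: both normalised gradient fields vanish, so the
        # integrand is 1 at every one of the 63 pixels
        brute = 0.5 * sum(1.0 for _ in range(r.size))
        assert d == pytest.approx(brute)

    def test_identical_images_score_below_misaligned_copy(self, rng):
        img = smooth_random_image(rng, (24, 24), sigma=2.0, scale=100.0)
        aligned = ngf_distance(img, img)
        shifted = ngf_distance(img, np.roll(img, 3, axis=1))
        assert aligned < shifted

    def test_invariant_to_intensity_inversion(self, rng):
        img = smooth_random_image(rng, (16, 16), sigma=1.5, scale=10.0)
        d_self = ngf_distance(img, img)
        d_inv = ngf_distance(img, -img)
        assert d_inv == pytest.approx(d_self, rel=1e-12)

    @pytest.mark.parametrize("c", [3.0, 0.2, -1.0, -7.5])
    def test_invariant_to_nonzero_rescaling(self, rng, c):
        img = smooth_random_image(rng, (16, 16), sigma=1.5, scale=10.0)
        other = smooth_random_image(rng, (16, 16), sigma=1.5, scale=10.0)
        assert ngf_distance(img, c * other) == pytest.approx(
            ngf_distance(img, other), rel=1e-10
        )
        assert ngf_distance(c * img, other) == pytest.approx(
            ngf_distance(img, other), rel=1e-10
        )

    def test_within_bounds(self, rng):
        img = smooth_random_image(rng, (10, 10))
        other = smooth_random_image(rng, (10, 10))
        d = ngf_distance(img, other)
        assert 0.0 <= d <= img.size / 2.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ngf_distance(np.zeros((8, 8)), np.zeros((8, 9)))


# ---------------------------------------------------------------------------
# elastic potential and operator


def elastic_potential_brute(u, mu, lam):
    """Independent stencil-by-stencil evaluation of the elastic energy."""
    d0u0, d1u0 = np.gradient(u[..., 0])
    d0u1, d1u1 = np.gradient(u[..., 1])
    total = 0.0
    for i in range(u.shape[0]):
        for j in range(u.shape[1]):
            sym = (
                (2 * d0u0[i, j]) ** 2
                + (d1u0[i, j] + d0u1[i, j]) ** 2
                + (d0u1[i, j] + d1u0[i, j]) ** 2
                + (2 * d1u1[i, j]) ** 2
            )
            div = d0u0[i, j] + d1u1[i, j]
            total += mu / 4.0 * sym + lam / 2.0 * div**2
    return total


class TestElasticPotential:
    def test_zero_for_zero_and_constant_fields(self):
        assert elastic_potential(np.zeros((6, 6, 2))) == 0.0
        const = np.broadcast_to([1.3, -0.4], (6, 6, 2)).copy()
        assert elastic_potential(const) == 0.0

    def test_linear_stretch_matches_closed_form(self):
        # u = (0, a*x): uniform stretch along the column axis
        a = 0.37
        n = 8
        xx = np.tile(np.arange(float(n)), (n, 1))
        u = np.stack([np.zeros((n, n)), a * xx], axis=-1)
        mu, lam = 1.4, 0.6
        expected = (mu * a**2 + lam / 2.0 * a**2) * n * n
        assert elastic_potential(u, mu, lam) == pytest.approx(expected)

    def test_matches_brute_force_on_random_field(self, rng):
        u = rng.standard_normal((7, 6, 2))
        assert elastic_potential(u, 1.3, 0.7) == pytest.approx(
            elastic_potential_brute(u, 1.3, 0.7)
        )

    def test_positive_for_nonrigid_field(self, rng):
        u = rng.standard_normal((6, 6, 2))
        assert elastic_potential(u, mu=1.0, lam=0.0) > 0


class TestElasticOperator:
    def test_annihilates_constant_fields(self):
        L = assemble_elastic_operator((7, 9), mu=1.0, lam=0.5)
        const = np.concatenate([np.full(63, 2.0), np.full(63, -1.0)])
        assert np.allclose(L @ const, 0.0, atol=1e-12)

    def test_symmetry(self, rng):
        L = assemble_elastic_operator((5, 6), mu=1.2, lam=0.3)
        v = rng.standard_normal(60)
        w = rng.standard_normal(60)
        assert v @ (L @ w) == pytest.approx(w @ (L @ v))

    def test_quadratic_form_is_twice_the_potential(self, rng):
        mu, lam = 0.9, 1.1
        L = assemble_elastic_operator((6, 6), mu=mu, lam=lam)
        u = rng.standard_normal((6, 6, 2))
        flat = np.concatenate([u[..., 0].ravel(), u[..., 1].ravel()])
        assert flat @ (L @ flat) == pytest.approx(2.0 * elastic_potential(u, mu, lam))


# ---------------------------------------------------------------------------
# similarity force


class TestSimilarityForce:
    def test_matches_finite_difference_gradient(self, rng):
        r = smooth_random_image(rng, (8, 8))
        t = smooth_random_image(rng, (8, 8))
        u = 0.3 * np.stack(
            [smooth_random_image(rng, (8, 8)), smooth_random_image(rng, (8, 8))], axis=-1
        )
        eps = (estimate_epsilon(r), estimate_epsilon(t))
        force = similarity_force(r, t, u, eps)
        h = 1e-4
        fd = np.zeros_like(force)
        for i in range(8):
            for j in range(8):
                for k in range(2):
                    up, um = u.copy(), u.copy()
                    up[i, j, k] += h
                    um[i, j, k] -= h
                    fd[i, j, k] = (
                        ngf_distance(r, t, up, eps) - ngf_distance(r, t, um, eps)
                    ) / (2 * h)
        scale = np.abs(force).max()
        assert np.allclose(force, fd, rtol=1e-4, atol=1e-4 * scale)

    def test_small_at_alignment_compared_to_misalignment(self, rng):
        img = smooth_random_image(rng, (24, 24), sigma=2.0, scale=50.0)
        eps = (estimate_epsilon(img), estimate_epsilon(img))
        aligned = similarity_force(img, img, None, eps)
        moved = similarity_force(img, np.roll(img, 2, axis=0), None, eps)
        assert np.abs(aligned).max() < np.abs(moved).max()

    def test_points_against_true_misalignment(self, rng):
        yy, xx = np.mgrid[0:32, 0:32]
        blob = np.exp(-((yy - 16.0) ** 2 + (xx - 16.0) ** 2) / 30.0) * 100.0
        shift = np.array([1.5, -1.0])
        moved = ndshift(blob, shift, order=3, mode="nearest")
        eps = (estimate_epsilon(blob), estimate_epsilon(moved))
        force = similarity_force(blob, moved, None, eps)
        # the displacement that aligns moved onto blob is +shift at every
        # pixel: the gradient must have negative inner product with it
        inner = float(np.sum(force[..., 0] * shift[0] + force[..., 1] * shift[1]))
        assert inner < 0


# ---------------------------------------------------------------------------
# warp


def bilinear_oracle(img, u):
    h, w = img.shape
    out = np.empty_like(img, dtype=float)
    for i in range(h):
        for j in range(w):
            y = min(max(i + u[i, j, 0], 0.0), h - 1.0)
            x = min(max(j + u[i, j, 1], 0.0), w - 1.0)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
            fy, fx = y - y0, x - x0
            out[i, j] = (
                img[y0, x0] * (1 - fy) * (1 - fx)
                + img[y1, x0] * fy * (1 - fx)
                + img[y0, x1] * (1 - fy) * fx
                + img[y1, x1] * fy * fx
            )
    return out


class TestWarp:
    def test_zero_field_is_identity(self, rng):
        img = rng.standard_normal((12, 13))
        assert np.array_equal(warp(img, np.zeros((12, 13, 2))), img)

    def test_integer_translation_shifts_exactly(self, rng):
        img = rng.standard_normal((10, 10))
        u = np.broadcast_to([2.0, -1.0], (10, 10, 2)).copy()
        out = warp(img, u, order=1)
        # interior pixels: out[i, j] = img[i + 2, j - 1]
        assert np.allclose(out[:-2, 1:], img[2:, :-1])

    def test_matches_loop_bilinear_oracle(self, rng):
        img = rng.standard_normal((16, 16))
        u = 0.8 * np.stack(
            [smooth_random_image(rng, (16, 16)), smooth_random_image(rng, (16, 16))],
            axis=-1,
        )
        assert np.allclose(warp(img, u, order=1), bilinear_oracle(img, u), atol=1e-10)


# ---------------------------------------------------------------------------
# solvers


class TestSolveLevel:
    def test_identical_images_stay_put(self, params):
        img = np.tile(np.arange(32.0), (32, 1)) + np.arange(32.0)[:, None]
        u = solve_level(img, img, np.zeros((32, 32, 2)), params)
        assert np.abs(u).max() < params.update_tolerance

    def test_translated_blob_recovered_within_one_pixel(self, rng, params):
        yy, xx = np.mgrid[0:48, 0:48]
        blob = np.exp(-((yy - 24.0) ** 2 + (xx - 24.0) ** 2) / 80.0) * 100.0
        blob += smooth_random_image(rng, (48, 48), sigma=3.0, scale=15.0)
        shift = (2.0, -2.0)
        moved = ndshift(blob, shift, order=3, mode="nearest")
        u = solve_level(blob, moved, np.zeros((48, 48, 2)), params)
        support = blob > 30.0
        err = np.hypot(u[..., 0] - shift[0], u[..., 1] - shift[1])
        assert err[support].mean() < 1.0

    def test_joint_functional_non_increasing(self, rng, params):
        img = smooth_random_image(rng, (32, 32), sigma=2.0, scale=100.0)
        moved = ndshift(img, (2.0, 1.0), order=3, mode="nearest")
        _, history = solve_level(
            img, moved, np.zeros((32, 32, 2)), params, return_history=True
        )
        assert len(history) > 1
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))


class TestRegister:
    def test_identity_returns_negligible_field(self, tissue_image128, params):
        img, _ = tissue_image128
        u = register(img, img, params)
        assert np.abs(u).max() < params.update_tolerance

    @pytest.mark.parametrize("shift", [(2.0, 1.5), (3.5, -4.0)])
    def test_translation_recovered_inside_tissue(self, tissue_image128, params, shift):
        img, mask = tissue_image128
        moved = ndshift(img, shift, order=3, mode="nearest")
        u = register(img, moved, params)
        err = np.hypot(u[..., 0] - shift[0], u[..., 1] - shift[1])
        assert err[mask].mean() < 1.0

    def test_smooth_elastic_warp_recovered(self, tissue_image128, params):
        img, mask = tissue_image128
        yy, xx = np.mgrid[0:128, 0:128]
        amp = 4.0
        u_true = np.stack(
            [
                amp * np.sin(2 * np.pi * yy / 96) * np.cos(2 * np.pi * xx / 128),
                0.8 * amp * np.cos(2 * np.pi * yy / 128) * np.sin(2 * np.pi * xx / 96),
            ],
            axis=-1,
        )
        moved = warp(img, u_true, order=3)
        # ground truth for the recovered (correction) field is the inverse warp
        v = -u_true.copy()
        for _ in range(10):
            v = -np.stack([warp(u_true[..., 0], v), warp(u_true[..., 1], v)], axis=-1)
        u = register(img, moved, params)
        err = np.hypot(u[..., 0] - v[..., 0], u[..., 1] - v[..., 1])
        assert err[mask].mean() < 1.5

    def test_upsampled_field_doubles_displacement(self):
        u = np.broadcast_to([1.5, -2.0], (16, 16, 2)).copy()
        up = _upsample_field(u, (32, 32))
        assert up.shape == (32, 32, 2)
        assert np.allclose(up[..., 0], 3.0)
        assert np.allclose(up[..., 1], -4.0)

    def test_small_image_reduces_pyramid_depth_with_warning(self, rng):
        img = smooth_random_image(rng, (40, 40), sigma=2.0, scale=50.0)
        moved = np.roll(img, 1, axis=0)
        with pytest.warns(RuntimeWarning, match="pyramid depth"):
            register(img, moved, RegistrationParams(n_levels=4))
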