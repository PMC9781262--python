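"""Fractional coefficient generation, 1-D operator, and gradient fields."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from fcnlm import (
    directional_masks,
    fcfds_1d,
    fractional_gradients,
    grunwald_coeffs,
    mask_coeffs,
    rho_weights,
    shifted_grunwald_1d,
)


def grunwald_closed_form(alpha: float, K: int) -> np.ndarray:
    """Independent oracle: g_k = Gamma(k - alpha)/(Gamma(-alpha) Gamma(k + 1)) via log-Gamma.

    For alpha in (0, 1), Gamma(-alpha) < 0 while Gamma(k - alpha) > 0 for
    k >= 1, so every g_k with k >= 1 is negative; magnitudes are computed
    in log space to stay stable out to large k.
    """
    out = np.empty(K + 1)
    out[0] = 1.0
    log_abs_gamma_neg_alpha = math.lgamma(-alpha) if alpha < 1 else None
    for k in range(1, K + 1):
        if log_abs_gamma_neg_alpha is None:  # alpha == 1: expansion of (1 - z)
            out[k] = -1.0 if k == 1 else 0.0
        else:
            out[k] = -math.exp(
                math.lgamma(k - alpha) - log_abs_gamma_neg_alpha - math.lgamma(k + 1)
            )
    return out


def moment_condition_solve(alpha: float) -> np.ndarray:
    """Independent oracle: solve the 3x3 moment-condition system for the rho weights."""
    r = np.array([0.0, -1.0, -2.0])
    A = np.vstack([np.ones(3), r, r**2])
    b = np.array([1.0, alpha / 2.0, alpha**2 / 4.0 - alpha / 12.0])
    return np.linalg.solve(A, b)


class TestGrunwaldCoeffs:
    @pytest.mark.parametrize(
        "alpha, K, expected",
        [
            (0.3, 0, [1.0]),
            (1.0, 3, [1.0, -1.0, 0.0, 0.0]),
            (0.5, 2, [1.0, -0.5, -0.125]),
        ],
    )
    def test_examples(self, alpha, K, expected):
        np.testing.assert_allclose(grunwald_coeffs(alpha, K), expected, atol=1e-15)

    @pytest.mark.parametrize("alpha", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_recurrence_matches_log_gamma_closed_form(self, alpha):
        g = grunwald_coeffs(alpha, 512)
        ref = grunwald_closed_form(alpha, 512)
        np.testing.assert_allclose(g, ref, rtol=1e-10, atol=1e-300)

    @given(alpha=st.floats(0.05, 0.95))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_sign_and_partial_sum_properties(self, alpha):
        g = grunwald_coeffs(alpha, 200)
        assert g[0] == 1.0
        assert np.isclose(g[1], -alpha)
        assert np.all(g[1:] < 0)
        partial = np.cumsum(g)
        # partial sums shrink in magnitude toward 0 (derivative of constants -> 0)
        assert np.all(np.diff(np.abs(partial)) <= 1e-15)
        assert abs(partial[-1]) < abs(partial[0])

    @pytest.mark.parametrize("bad_alpha", [0.0, -0.2, 1.5, float("nan")])
    def test_domain_errors(self, bad_alpha):
        with pytest.raises(ValueError):
            grunwald_coeffs(bad_alpha, 4)
        with pytest.raises(ValueError):
            grunwald_coeffs(0.5, -1)


class TestRhoWeights:
    @pytest.mark.parametrize("alpha", [0.1, 0.25, 0.5, 0.75, 0.9, 1.0])
    def test_moment_conditions(self, alpha):
        rho = np.array(rho_weights(alpha))
        np.testing.assert_allclose(rho, moment_condition_solve(alpha), atol=1e-12)
        r = np.array([0.0, -1.0, -2.0])
        assert abs(rho.sum() - 1.0) < 1e-12
        assert abs(rho @ r - alpha / 2.0) < 1e-12
        assert abs(rho @ r**2 - (alpha**2 / 4.0 - alpha / 12.0)) < 1e-12

    def test_classical_limit(self):
        rho = rho_weights(1.0)
        np.testing.assert_allclose(rho, [11.0 / 6.0, -7.0 / 6.0, 1.0 / 3.0], atol=1e-14)

    def test_half_order_values(self):
        rho = rho_weights(0.5)
        assert np.isclose(rho.rho1, 1.385417, atol=5e-7)
        assert np.isclose(rho.rho3, 0.135417, atol=5e-7)
        assert np.isclose(rho.rho2, 1.0 - rho.rho1 - rho.rho3, atol=1e-14)

    @pytest.mark.parametrize("alpha", [0.1, 0.4, 0.8, 1.0])
    def test_signs(self, alpha):
        rho = rho_weights(alpha)
        assert rho.rho1 > 0 and rho.rho3 > 0 and rho.rho2 < 0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            rho_weights(1.2)


class TestMaskCoeffs:
    def test_classical_backward_difference(self):
        c = mask_coeffs(1.0, 4)
        np.testing.assert_allclose(c, [11.0 / 6.0, -3.0, 1.5, -1.0 / 3.0], atol=1e-14)

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.9])
    @pytest.mark.parametrize("N", [2, 4, 8])
    def test_leading_coefficients(self, alpha, N):
        c = mask_coeffs(alpha, N)
        rho = rho_weights(alpha)
        assert c.size == N
        assert np.isclose(c[0], rho.rho1, atol=1e-14)
        assert np.isclose(c[1], -alpha * rho.rho1 + rho.rho2, atol=1e-14)

    @pytest.mark.parametrize("N", [4, 6, 10])
    def test_classical_limit_conserves_constants(self, N):
        # at alpha = 1 the stencil is a first-derivative scheme: sum of taps is 0
        assert abs(mask_coeffs(1.0, N).sum()) < 1e-12

    @pytest.mark.parametrize("bad_N", [0, 1, 3, -2])
    def test_length_errors(self, bad_N):
        with pytest.raises(ValueError):
            mask_coeffs(0.5, bad_N)


def rl_derivative_x4(x: np.ndarray, alpha: float) -> np.ndarray:
    """Closed-form fractional derivative of x^4 (lower terminal 0)."""
    return math.gamma(5) / math.gamma(5 - alpha) * x ** (4 - alpha)


class TestFcfds1d:
    @pytest.mark.parametrize("alpha", [0.3, 0.7])
    def test_constant_signal(self, alpha):
        v0, spacing, L = 3.5, 0.25, 12
        out = fcfds_1d(np.full(L, v0), alpha, spacing).values
        g = grunwald_coeffs(alpha, L - 1)
        rho = rho_weights(alpha)
        S = np.cumsum(g)
        expected = rho.rho1 * S
        expected[1:] += rho.rho2 * S[:-1]
        expected[2:] += rho.rho3 * S[:-2]
        expected *= v0 * spacing ** (-alpha)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_matches_closed_form_on_quartic(self):
        alpha, h = 0.5, 1.0 / 256
        x = np.arange(0.0, 1.0 + h / 2, h)
        est = fcfds_1d(x**4, alpha, h).values
        exact = rl_derivative_x4(x, alpha)
        assert abs(est[-1] - exact[-1]) < 5e-6

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.8])
    def test_third_order_convergence(self, alpha):
        spacings = [1.0 / 64, 1.0 / 128, 1.0 / 256]
        errs = []
        for h in spacings:
            x = np.arange(0.0, 1.0 + h / 2, h)
            errs.append(abs(fcfds_1d(x**4, alpha, h).values[-1] - rl_derivative_x4(x, alpha)[-1]))
        slope = np.polyfit(np.log(spacings), np.log(errs), 1)[0]
        assert abs(slope - 3.0) < 0.3

    def test_plain_grunwald_is_first_order(self):
        alpha = 0.5
        spacings = [1.0 / 64, 1.0 / 128, 1.0 / 256]
        errs = []
        for h in spacings:
            x = np.arange(0.0, 1.0 + h / 2, h)
            errs.append(abs(shifted_grunwald_1d(x**4, alpha, h)[-1] - rl_derivative_x4(x, alpha)[-1]))
        slope = np.polyfit(np.log(spacings), np.log(errs), 1)[0]
        assert abs(slope - 1.0) < 0.3

    def test_boundary_metadata_and_errors(self):
        res = fcfds_1d(np.arange(5.0), 0.5, 1.0)
        assert res.n_boundary == 2
        with pytest.raises(ValueError):
            fcfds_1d(np.array([1.0, 2.0]), 0.5, 1.0)
        with pytest.raises(ValueError):
            fcfds_1d(np.arange(5.0), 0.5, 0.0)


class TestFractionalGradients:
    def test_constant_image(self):
        masks = directional_masks(0.5, 4)
        img = np.full((16, 20), 6.0)
        grads = fractional_gradients(img, masks)
        expected = 6.0 * masks.c.sum()
        np.testing.assert_allclose(grads.dx, expected, rtol=1e-12)
        np.testing.assert_allclose(grads.dy, expected, rtol=1e-12)
        assert grads.dx.shape == img.shape and grads.dy.shape == img.shape

    def test_classical_limit_exact_on_cubic_rows(self):
        masks = directional_masks(1.0, 4)
        cols = np.arange(24.0)
        poly = 2 * cols**3 - 3 * cols**2 + cols
        img = np.tile(poly, (8, 1))
        dx = fractional_gradients(img, masks).dx
        exact = 6 * cols**2 - 6 * cols + 1
        np.testing.assert_allclose(dx[:, 3:], np.tile(exact, (8, 1))[:, 3:], rtol=1e-10)

    def test_impulse_reproduces_stencil(self):
        masks = directional_masks(0.4, 4)
        img = np.zeros((15, 15))
        img[7, 5] = 1.0
        grads = fractional_gradients(img, masks)
        np.testing.assert_allclose(grads.dx[7, 5:9], masks.c, atol=1e-14)
        np.testing.assert_allclose(grads.dy[7:11, 5], masks.c, atol=1e-14)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_linearity_and_shift_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 20, 20))
        masks = directional_masks(0.6, 4)
        gx = lambda im: fractional_gradients(im, masks).dx
        np.testing.assert_allclose(gx(2.0 * a - 3.0 * b), 2.0 * gx(a) - 3.0 * gx(b), atol=1e-10)
        shifted = np.roll(a, 2, axis=1)
        interior = (slice(None), slice(6, 18))
        np.testing.assert_allclose(
            gx(shifted)[interior], np.roll(gx(a), 2, axis=1)[interior], atol=1e-10
        )

    def test_one_sided_directionality_under_rotation(self):
        """180-degree rotation commutes with the gradient only if the stencil is reversed."""
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 255, size=(24, 24))
        masks = directional_masks(0.5, 4)
        rot = lambda a: a[::-1, ::-1]
        dx_rot = rot(fractional_gradients(rot(img), masks).dx)
        dx_fwd = fractional_gradients(img, masks).dx
        # not equivariant as-is ...
        assert not np.allclose(dx_rot, dx_fwd)
        # ... but equals the correlation with the reversed (forward-looking) stencil
        w = np.concatenate([np.zeros(masks.N - 1), masks.c])
        expected = ndimage.correlate1d(img, w, axis=1, mode="nearest")
        np.testing.assert_allclose(dx_rot, expected, atol=1e-10)

    def test_too_small_image(self):
        with pytest.raises(ValueError):
            fractional_gradients(np.ones((3, 10)), directional_masks(0.5, 4))
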