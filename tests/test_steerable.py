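"""Kernel construction, steering coefficients and the rotated-kernel oracle."""

import math

import numpy as np
import pytest
from scipy import ndimage

from graintex.errors import ImageSizeError, InvalidParameterError
from graintex.steerable import (
    GaussianDerivativeSpec,
    SteerableTemplate,
    TemplateTerm,
    base_responses,
    builtin_template_names,
    evaluate_template_kernel,
    gaussian_derivative_kernel,
    get_template,
    oriented_response,
    steering_coefficients,
)


def brute_force_convolve(image, kernel):
    """Direct spatial convolution with mirror padding — the independent oracle."""
    h = kernel.shape[0] // 2
    padded = np.pad(image, h, mode="reflect")  # matches ndimage 'mirror'
    flipped = kernel[::-1, ::-1]
    out = np.empty_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = np.sum(padded[i : i + 2 * h + 1, j : j + 2 * h + 1] * flipped)
    return out


class TestGaussianDerivativeKernel:
    def test_smoothing_kernel_has_unit_mass(self):
        k = gaussian_derivative_kernel(GaussianDerivativeSpec(0, 0, 1.0), truncation=4)
        assert abs(k.values.sum() - 1.0) < 1e-5
        assert k.values.shape == (9, 9)
        assert k.center == (4, 4)

    def test_first_derivative_is_antisymmetric_with_zero_sum(self):
        k = gaussian_derivative_kernel(GaussianDerivativeSpec(1, 0, 1.0))
        assert abs(k.values.sum()) < 1e-12
        np.testing.assert_allclose(k.values, -k.values[:, ::-1], atol=1e-15)

    def test_second_derivative_center_matches_closed_form(self):
        # d2/dx2 of the unit 2-D Gaussian at the origin: -1/(2*pi*sigma^4)
        k = gaussian_derivative_kernel(GaussianDerivativeSpec(2, 0, 1.0))
        assert k.values[k.center] == pytest.approx(-1.0 / (2.0 * math.pi), abs=1e-12)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            GaussianDerivativeSpec(1, 0, -1.0)

    @pytest.mark.parametrize("sigma", [0.5, 1.3])
    def test_extent_follows_truncation_rule(self, sigma):
        k = gaussian_derivative_kernel(GaussianDerivativeSpec(0, 1, sigma), truncation=4)
        half = math.ceil(4 * sigma)
        assert k.values.shape == (2 * half + 1, 2 * half + 1)


class TestBaseResponses:
    def test_constant_image_gives_zero_derivative_responses(self):
        t = get_template("T3")
        br = base_responses(np.full((32, 32), 0.7), t, sigma=1.0)
        for arr in br.responses.values():
            assert np.max(np.abs(arr)) < 1e-9

    def test_ramp_image_recovers_unit_gradient(self):
        xs = np.tile(np.arange(48, dtype=float), (48, 1))
        t = get_template("T2")  # span includes orders 1 and 3
        br = base_responses(xs, t, sigma=1.0)
        interior = (slice(8, -8), slice(8, -8))
        np.testing.assert_allclose(br.responses[(1, 0)][interior], 1.0, atol=1e-3)
        np.testing.assert_allclose(br.responses[(0, 1)][interior], 0.0, atol=1e-9)
        # higher-order responses of a linear function vanish up to kernel
        # discretization error (sampled derivative kernels are not exactly
        # moment-free on the integer grid)
        for (a, b), arr in br.responses.items():
            if a + b >= 2:
                np.testing.assert_allclose(arr[interior], 0.0, atol=5e-3)

    def test_separable_convolution_matches_dense_oracle(self, random_image):
        img = random_image[:32, :32]
        t = get_template("T4")
        br = base_responses(img, t, sigma=1.0)
        for (a, b), arr in br.responses.items():
            kern = gaussian_derivative_kernel(GaussianDerivativeSpec(a, b, 1.0))
            expected = brute_force_convolve(img, kern.values)
            np.testing.assert_allclose(arr, expected, atol=1e-10)

    def test_image_smaller_than_kernel_rejected(self):
        with pytest.raises(ImageSizeError):
            base_responses(np.zeros((8, 8)), get_template("T1"), sigma=2.0)

    def test_span_covers_all_same_order_pairs(self):
        t = get_template("T2")  # names (0,1) and (2,1) only
        br = base_responses(np.zeros((32, 32)), t, sigma=1.0)
        assert set(br.responses) == {(1, 0), (0, 1), (3, 0), (2, 1), (1, 2), (0, 3)}


class TestSteeringCoefficients:
    def test_identity_rotation_returns_folded_template_weights(self):
        t = get_template("T2")
        alpha = steering_coefficients(t, 0.0, sigma=2.0)
        assert alpha[(0, 1)] == pytest.approx(-0.966)
        assert alpha[(2, 1)] == pytest.approx(-0.256 * 4.0)
        for pair in [(1, 0), (3, 0), (1, 2), (0, 3)]:
            assert alpha[pair] == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("theta", [0.3, 1.1, 2.9])
    def test_single_gy_term_rotates_by_chain_rule(self, theta):
        t = SteerableTemplate("gy", (TemplateTerm(2.5, 0, 0, 1),))
        alpha = steering_coefficients(t, theta, sigma=1.0)
        assert alpha[(1, 0)] == pytest.approx(-math.sin(theta) * 2.5)
        assert alpha[(0, 1)] == pytest.approx(math.cos(theta) * 2.5)

    @pytest.mark.parametrize("name", builtin_template_names())
    def test_half_turn_applies_order_parity(self, name):
        t = get_template(name)
        a0 = steering_coefficients(t, 0.0, sigma=1.0)
        api = steering_coefficients(t, math.pi, sigma=1.0)
        for pair, v in a0.items():
            m = pair[0] + pair[1]
            assert api[pair] == pytest.approx((-1) ** m * v, abs=1e-12)


class TestOrientedResponse:
    def test_zero_angle_reduces_to_direct_term_combination(self, random_image):
        t = get_template("T5")
        base = base_responses(random_image, t, sigma=1.0)
        resp = oriented_response(random_image, t, 1.0, 0.0, base=base).values
        manual = np.zeros_like(random_image)
        for pair, w in t.folded_weights(1.0).items():
            manual += w * base.responses[pair]
        np.testing.assert_allclose(resp, manual, atol=1e-12)

    @pytest.mark.parametrize("name", ["T1", "T5"])
    def test_steered_response_matches_rotated_kernel_convolution(self, name, random_image):
        t = get_template(name)
        sigma = 1.0
        base = base_responses(random_image, t, sigma)
        for theta in np.arange(8) * math.pi / 8:
            steered = oriented_response(random_image, t, sigma, theta, base=base).values
            kern = evaluate_template_kernel(t, sigma, theta)
            direct = ndimage.convolve(random_image, kern.values, mode="mirror")
            h = kern.center[0]
            a, b = steered[h:-h, h:-h], direct[h:-h, h:-h]
            assert np.max(np.abs(a - b)) / np.max(np.abs(b)) < 1e-6

    def test_linearity_in_the_image(self, random_image):
        t = get_template("T6")
        img2 = np.cos(random_image)
        r1 = oriented_response(random_image, t, 1.0, 0.7).values
        r2 = oriented_response(img2, t, 1.0, 0.7).values
        r12 = oriented_response(3.0 * random_image - 2.0 * img2, t, 1.0, 0.7).values
        np.testing.assert_allclose(r12, 3.0 * r1 - 2.0 * r2, atol=1e-10)

    def test_weight_scaling_scales_response_exactly(self, random_image):
        t = get_template("T1")
        scaled = SteerableTemplate(
            "T1x", tuple(TemplateTerm(5.0 * tt.weight, tt.sigma_exponent, tt.dx_order, tt.dy_order) for tt in t.terms)
        )
        r = oriented_response(random_image, t, 1.0, 0.4).values
        rs = oriented_response(random_image, scaled, 1.0, 0.4).values
        np.testing.assert_allclose(rs, 5.0 * r, rtol=1e-12, atol=1e-14)

    @pytest.mark.parametrize("name", builtin_template_names())
    def test_period_pi_up_to_parity_sign(self, name, random_image):
        t = get_template(name)
        theta = 0.9
        r = oriented_response(random_image, t, 1.0, theta).values
        rpi = oriented_response(random_image, t, 1.0, theta + math.pi).values
        orders = t.orders
        if len(orders) == 1 or all(o % 2 == orders[0] % 2 for o in orders):
            sign = (-1) ** orders[0]
            np.testing.assert_allclose(rpi, sign * r, atol=1e-10)
        else:
            # mixed parity (T6): odd and even blocks flip independently
            assert not np.allclose(rpi, r)

    def test_rotational_symmetry_of_isotropic_blob(self):
        yy, xx = np.mgrid[:65, :65] - 32.0
        blob = np.exp(-(xx**2 + yy**2) / (2 * 6.0**2))
        t = get_template("T1")
        base = base_responses(blob, t, 1.0)
        quantiles = []
        levels = np.linspace(0.1, 0.99, 10)
        for theta in np.arange(8) * math.pi / 8:
            r = oriented_response(blob, t, 1.0, theta, base=base).values
            quantiles.append(np.quantile(np.abs(r[8:-8, 8:-8]), levels))
        scale = np.max(quantiles[0])
        for q in quantiles[1:]:
            # grid sampling of the blob breaks exact rotational symmetry at
            # the few-percent level; the magnitude distribution must agree
            np.testing.assert_allclose(q, quantiles[0], atol=0.05 * scale)


def test_wedge_template_respects_phi_parameter():
    t_quarter = get_template("T6", phi=math.pi / 2)
    t_full = get_template("T6", phi=math.pi)
    assert t_quarter.extra_params["phi"] == pytest.approx(math.pi / 2)
    assert t_quarter.terms[0].weight != t_full.terms[0].weight
    # phi = pi kills the second-order part: cos(phi/2) = 0
    assert t_full.terms[1].weight == pytest.approx(0.0, abs=1e-16)
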