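"""Steerable Gaussian-derivative filtering.

A mixed Gaussian-derivative template ``G = sum_m sum_i k_{m,i} d^i_x d^{m-i}_y G_sigma``
is *steerable*: its response at any orientation theta is an exact linear combination of
the responses to the axis-aligned derivative kernels of the same total orders. This
module constructs the analytic kernels, holds the six built-in edge / ridge / wedge
templates used for grain-image texture analysis, derives the steering coefficients by
symbolic rotation of the derivative operators, and evaluates oriented responses as
weighted sums of a small set of base convolutions.

Coordinate convention (used everywhere, including the synthetic generators):
``x`` runs along axis 1 (columns), ``y`` along axis 0 (rows); theta is measured
counter-clockwise from the +x axis toward +y and responses have period pi up to the
parity sign ``(-1)^m`` of each order-``m`` term, so orientation sampling lives in
``[0, pi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import ImageSizeError, InvalidParameterError

__all__ = [
    "GaussianDerivativeSpec",
    "TemplateTerm",
    "SteerableTemplate",
    "Kernel",
    "BaseResponseSet",
    "OrientedResponse",
    "gaussian_derivative_kernel",
    "evaluate_template_kernel",
    "base_responses",
    "steering_coefficients",
    "oriented_response",
    "get_template",
    "builtin_template_names",
    "kernel_half_width",
]

DEFAULT_TRUNCATION = 4.0


# ---------------------------------------------------------------------------
# Analytic 1-D Gaussian derivatives
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _deriv_poly_coeffs(order: int) -> tuple[float, ...]:
    """Coefficients of p_n with d^n/dt^n g(t; s) = p_n(t / s) / s^n * g(t; s).

    Working in the scaled variable u = t/s keeps the recurrence sigma-free:
    p_0 = 1 and p_{n+1}(u) = p_n'(u) - u * p_n(u)  (a Hermite-type recurrence).
    """
    coeffs = np.array([1.0])
    for _ in range(order):
        deriv = np.polynomial.polynomial.polyder(coeffs) if len(coeffs) > 1 else np.array([0.0])
        shifted = np.concatenate([[0.0], coeffs])  # u * p_n(u)
        n = max(len(deriv), len(shifted))
        new = np.zeros(n)
        new[: len(deriv)] += deriv
        new[: len(shifted)] -= shifted
        coeffs = new
    return tuple(coeffs)


def _gauss_deriv_1d(t: np.ndarray, order: int, sigma: float) -> np.ndarray:
    """Evaluate d^order/dt^order of the unit-integral 1-D Gaussian at points t."""
    u = np.asarray(t, dtype=float) / sigma
    poly = np.polynomial.polynomial.polyval(u, np.asarray(_deriv_poly_coeffs(order)))
    g = np.exp(-0.5 * u * u) / (math.sqrt(2.0 * math.pi) * sigma)
    return poly * g / sigma**order


def kernel_half_width(sigma: float, truncation: float = DEFAULT_TRUNCATION) -> int:
    return int(math.ceil(truncation * sigma))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianDerivativeSpec:
    """One axis-aligned mixed derivative of the isotropic 2-D Gaussian."""

    dx_order: int
    dy_order: int
    sigma: float

    def __post_init__(self) -> None:
        if self.dx_order < 0 or self.dy_order < 0:
            raise InvalidParameterError("derivative orders must be non-negative")
        if not (self.sigma > 0):
            raise InvalidParameterError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class Kernel:
    """Discretized kernel with odd extent and its geometric center."""

    values: np.ndarray
    center: tuple[int, int]
    sigma: float


@dataclass(frozen=True)
class TemplateTerm:
    """One weighted derivative term: weight * sigma**sigma_exponent * d^i_x d^j_y G."""

    weight: float
    sigma_exponent: int
    dx_order: int
    dy_order: int

    @property
    def order(self) -> int:
        return self.dx_order + self.dy_order


@dataclass(frozen=True)
class SteerableTemplate:
    """Named mixed Gaussian-derivative template (ordered list of weighted terms)."""

    name: str
    terms: tuple[TemplateTerm, ...]
    extra_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.terms:
            raise InvalidParameterError("a template needs at least one term")
        for t in self.terms:
            if t.dx_order < 0 or t.dy_order < 0:
                raise InvalidParameterError("derivative orders must be non-negative")
            if t.order < 1:
                raise InvalidParameterError(
                    "templates contain no pure-smoothing (order-0) term"
                )

    @property
    def orders(self) -> tuple[int, ...]:
        """Distinct total derivative orders present, ascending."""
        return tuple(sorted({t.order for t in self.terms}))

    def steering_span(self) -> tuple[tuple[int, int], ...]:
        """All (dx, dy) pairs mixed by steering: every split of every present order."""
        pairs = []
        for m in self.orders:
            pairs.extend((i, m - i) for i in range(m + 1))
        return tuple(pairs)

    def folded_weights(self, sigma: float) -> dict[tuple[int, int], float]:
        """Term weights with the sigma power folded in, summed per derivative pair."""
        out: dict[tuple[int, int], float] = {}
        for t in self.terms:
            key = (t.dx_order, t.dy_order)
            out[key] = out.get(key, 0.0) + t.weight * sigma**t.sigma_exponent
        return out


@dataclass(frozen=True)
class BaseResponseSet:
    """Convolutions of one image with every kernel in a template's steering span."""

    responses: Mapping[tuple[int, int], np.ndarray]
    sigma: float
    image_shape: tuple[int, int]


@dataclass(frozen=True)
class OrientedResponse:
    values: np.ndarray
    theta: float
    sigma: float
    template_name: str


# ---------------------------------------------------------------------------
# Kernel construction
# ---------------------------------------------------------------------------

def gaussian_derivative_kernel(
    spec: GaussianDerivativeSpec, truncation: float = DEFAULT_TRUNCATION
) -> Kernel:
    """Sample the analytic mixed Gaussian derivative on the integer grid.

    The 2-D isotropic Gaussian separates, so the kernel is the outer product of
    the 1-D derivative profiles along y (rows) and x (columns). Half-width is
    ceil(truncation * sigma) per axis, giving odd extent.
    """
    if truncation < 3:
        raise InvalidParameterError("truncation below 3 loses too much kernel mass")
    half = kernel_half_width(spec.sigma, truncation)
    coords = np.arange(-half, half + 1, dtype=float)
    kx = _gauss_deriv_1d(coords, spec.dx_order, spec.sigma)
    ky = _gauss_deriv_1d(coords, spec.dy_order, spec.sigma)
    return Kernel(values=np.outer(ky, kx), center=(half, half), sigma=spec.sigma)


def evaluate_template_kernel(
    template: SteerableTemplate,
    sigma: float,
    theta: float = 0.0,
    truncation: float = DEFAULT_TRUNCATION,
) -> Kernel:
    """Analytically sample the (rotated) template kernel on the integer grid.

    The rotated template is the axis-aligned derivative pattern evaluated at the
    rotated coordinates (x', y') = (cos(t) x + sin(t) y, -sin(t) x + cos(t) y).
    Used directly for brute-force oriented convolution and as the steering oracle.
    """
    if not (sigma > 0):
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    half = kernel_half_width(sigma, truncation)
    coords = np.arange(-half, half + 1, dtype=float)
    xg, yg = np.meshgrid(coords, coords)  # xg varies along columns, yg along rows
    c, s = math.cos(theta), math.sin(theta)
    xr = c * xg + s * yg
    yr = -s * xg + c * yg
    values = np.zeros_like(xg)
    for t in template.terms:
        w = t.weight * sigma**t.sigma_exponent
        values += w * _gauss_deriv_1d(xr, t.dx_order, sigma) * _gauss_deriv_1d(
            yr, t.dy_order, sigma
        )
    return Kernel(values=values, center=(half, half), sigma=sigma)


# ---------------------------------------------------------------------------
# Base responses and steering
# ---------------------------------------------------------------------------

def _convolve_separable(
    image: np.ndarray, dx_order: int, dy_order: int, sigma: float, truncation: float
) -> np.ndarray:
    """I * (d^i_x d^j_y G) as two 1-D convolutions with mirror boundary."""
    half = kernel_half_width(sigma, truncation)
    coords = np.arange(-half, half + 1, dtype=float)
    ky = _gauss_deriv_1d(coords, dy_order, sigma)
    kx = _gauss_deriv_1d(coords, dx_order, sigma)
    out = ndimage.convolve1d(image, ky, axis=0, mode="mirror")
    return ndimage.convolve1d(out, kx, axis=1, mode="mirror")


def base_responses(
    image: np.ndarray,
    template: SteerableTemplate,
    sigma: float,
    truncation: float = DEFAULT_TRUNCATION,
) -> BaseResponseSet:
    """Convolve the image with every axis-aligned kernel steering can mix in.

    Steering a rotated order-m term spreads over *all* (i, m-i) pairs of that
    order, not only the pairs the template names, so the full span is computed.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidParameterError("image must be a 2-D array")
    half = kernel_half_width(sigma, truncation)
    extent = 2 * half + 1
    if image.shape[0] < extent or image.shape[1] < extent:
        raise ImageSizeError(
            f"image {image.shape} smaller than kernel extent {extent} at sigma={sigma}"
        )
    responses = {
        pair: _convolve_separable(image, pair[0], pair[1], sigma, truncation)
        for pair in template.steering_span()
    }
    return BaseResponseSet(responses=responses, sigma=sigma, image_shape=image.shape)


def steering_coefficients(
    template: SteerableTemplate, theta: float, sigma: float
) -> dict[tuple[int, int], float]:
    """Coefficients alpha_{m,i}(theta) of the base responses for the rotated template.

    Each rotated operator is expanded with the substitution
    d_x' = cos(t) d_x + sin(t) d_y,  d_y' = -sin(t) d_x + cos(t) d_y
    and same-order monomials are collected; sigma-dependent term weights are folded
    in first. The result is a trigonometric polynomial in theta per coefficient.
    """
    if not math.isfinite(theta):
        raise InvalidParameterError("theta must be finite")
    c, s = math.cos(theta), math.sin(theta)
    alpha: dict[tuple[int, int], float] = {
        pair: 0.0 for pair in template.steering_span()
    }
    for term in template.terms:
        w = term.weight * sigma**term.sigma_exponent
        i, j = term.dx_order, term.dy_order
        for t in range(i + 1):
            for l in range(j + 1):
                coef = (
                    w
                    * math.comb(i, t) * c**t * s ** (i - t)
                    * math.comb(j, l) * (-s) ** l * c ** (j - l)
                )
                alpha[(t + l, (i - t) + (j - l))] += coef
    return alpha


def oriented_response(
    image: np.ndarray,
    template: SteerableTemplate,
    sigma: float,
    theta: float,
    base: BaseResponseSet | None = None,
    truncation: float = DEFAULT_TRUNCATION,
) -> OrientedResponse:
    """Template response at orientation theta as a weighted sum of base responses."""
    if base is None:
        base = base_responses(image, template, sigma, truncation)
    alpha = steering_coefficients(template, theta, sigma)
    values = np.zeros(base.image_shape, dtype=float)
    for pair, coef in alpha.items():
        if coef != 0.0:
            values += coef * base.responses[pair]
    return OrientedResponse(
        values=values, theta=theta % math.pi, sigma=sigma, template_name=template.name
    )


# ---------------------------------------------------------------------------
# Built-in template registry
# ---------------------------------------------------------------------------
#
# Six detectors are built in: T1-T3 are optimal edge detectors of increasing
# derivative order, T4-T5 ridge detectors, T6 a wedge detector with opening
# angle phi. Two printed leading constants are typographically ambiguous
# (plausibly dropped radical signs); `radical_constants=True` switches to the
# sqrt variants. A global rescaling of a template only rescales the location
# and scale of the fitted response distribution and leaves the Weibull shape
# untouched, so downstream texture features are robust to this choice.

def _t1(c1: float) -> SteerableTemplate:
    return SteerableTemplate("T1", (TemplateTerm(c1, 0, 0, 1),))


def _t2() -> SteerableTemplate:
    return SteerableTemplate(
        "T2", (TemplateTerm(-0.966, 0, 0, 1), TemplateTerm(-0.256, 2, 2, 1))
    )


def _t3() -> SteerableTemplate:
    return SteerableTemplate(
        "T3",
        (
            TemplateTerm(-1.0655, 0, 0, 1),
            TemplateTerm(-0.2, 2, 2, 1),
            TemplateTerm(-0.042, 2, 0, 3),
        ),
    )


def _t4(c4: float) -> SteerableTemplate:
    # c4 * sigma * (Gyy - Gxx / 3)
    return SteerableTemplate(
        "T4", (TemplateTerm(c4, 1, 0, 2), TemplateTerm(-c4 / 3.0, 1, 2, 0))
    )


def _t5() -> SteerableTemplate:
    return SteerableTemplate(
        "T5",
        (
            TemplateTerm(-0.204, 0, 0, 2),
            TemplateTerm(0.059, 1, 2, 0),
            TemplateTerm(0.063, 2, 0, 4),
            TemplateTerm(-0.194, 3, 2, 2),
            TemplateTerm(0.024, 3, 4, 0),
        ),
    )


def _t6(c6: float, phi: float) -> SteerableTemplate:
    # c6 * [Gx + sigma*cos(phi/2)/pi * (Gxx - Gyy)]
    w2 = c6 * math.cos(phi / 2.0) / math.pi
    return SteerableTemplate(
        "T6",
        (
            TemplateTerm(c6, 0, 1, 0),
            TemplateTerm(w2, 1, 2, 0),
            TemplateTerm(-w2, 1, 0, 2),
        ),
        extra_params={"phi": phi},
    )


def builtin_template_names() -> tuple[str, ...]:
    return ("T1", "T2", "T3", "T4", "T5", "T6")


def get_template(
    name: str,
    phi: float = math.pi / 2.0,
    radical_constants: bool = False,
) -> SteerableTemplate:
    """Look up a built-in template by name (``T1`` ... ``T6``).

    Parameters
    ----------
    phi : wedge opening angle of T6 (radians), default pi/2.
    radical_constants : use sqrt variants of the ambiguous printed leading
        constants of T1, T4 and T6 instead of the literal values.
    """
    name = name.upper()
    if name == "T1":
        c1 = -math.sqrt(2.0 / math.pi) if radical_constants else -2.0 / math.pi
        return _t1(c1)
    if name == "T2":
        return _t2()
    if name == "T3":
        return _t3()
    if name == "T4":
        c4 = -math.sqrt(3.0 / (4.0 * math.pi)) if radical_constants else -3.0 / (
            4.0 * math.pi
        )
        return _t4(c4)
    if name == "T5":
        return _t5()
    if name == "T6":
        denom = 2.0 + math.pi + 2.0 * math.cos(phi)
        c6 = -math.sqrt(2.0 / denom) if radical_constants else -2.0 / denom
        return _t6(c6, phi)
    raise InvalidParameterError(f"unknown template {name!r}; built-ins are T1..T6")


def template_from_terms(
    name: str,
    terms: list[tuple[float, int, int, int]],
    extra_params: Mapping[str, float] | None = None,
) -> SteerableTemplate:
    """Build a user template from (weight, sigma_exponent, dx_order, dy_order) rows."""
    tt = tuple(TemplateTerm(w, e, dx, dy) for (w, e, dx, dy) in terms)
    return SteerableTemplate(name, tt, extra_params or {})
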