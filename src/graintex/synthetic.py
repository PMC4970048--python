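"""Seeded generators for granular-product-like images and two-class feature datasets.

No public grain-image corpus exists, so every image-side operation is exercised on
rendered stand-ins: many anti-aliased, linearly shaded ellipses ("grains") packed on a
darker background with additive pixel noise. Orientation can be isotropic or
concentrated around a dominant angle, which gives the directional-feature tests a
ground truth. The classifier stack is exercised on two-Gaussian feature datasets with
a controllable label rate, mirroring a grading task where only a fraction of samples
carry laboratory-assigned quality labels.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classifiers import LabeledSet
from .cosc import UnlabeledSet
from .errors import InvalidParameterError, PackingError

__all__ = [
    "GranularImageSpec",
    "SSDatasetSpec",
    "generate_granular_image",
    "generate_ss_dataset",
]


@dataclass(frozen=True)
class GranularImageSpec:
    """Rendering recipe for a synthetic grain image (intensities in [0, 1])."""

    shape: tuple[int, int] = (128, 128)
    n_particles: int = 150
    axis_mean: float = 6.0
    axis_spread: float = 1.5
    aspect_ratio: float = 0.55  # minor/major axis mean ratio
    orientation: str = "isotropic"  # or "concentrated"
    orientation_angle: float = 0.0  # dominant angle when concentrated (radians)
    orientation_spread: float = 0.12
    foreground: float = 0.75
    background: float = 0.25
    shading: float = 0.35  # relative intensity ramp across each grain
    noise: float = 0.02
    overlap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 64:
            raise InvalidParameterError("image dimensions must be >= 64")
        if self.orientation not in ("isotropic", "concentrated"):
            raise InvalidParameterError("orientation must be isotropic|concentrated")
        if not (0 <= self.background <= 1 and 0 <= self.foreground <= 1):
            raise InvalidParameterError("intensities must lie in [0, 1]")


def generate_granular_image(spec: GranularImageSpec) -> np.ndarray:
    """Render shaded ellipses at random positions/orientations; reproducible by seed.

    Edges use anti-aliased sub-pixel coverage (~1 px ramp) so derivative filters see
    smooth gradients; each grain carries a linear Lambertian-like shading ramp along
    its major axis. Raises PackingError when non-overlapping placement fails.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    img = np.full(spec.shape, spec.background, dtype=float)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, radius)
    max_retries = 60
    for _ in range(spec.n_particles):
        for attempt in range(max_retries + 1):
            cy = rng.uniform(0, rows)
            cx = rng.uniform(0, cols)
            a = max(1.5, rng.normal(spec.axis_mean, spec.axis_spread))
            b = max(1.0, a * spec.aspect_ratio * rng.uniform(0.8, 1.2))
            if spec.orientation == "concentrated":
                theta = rng.normal(spec.orientation_angle, spec.orientation_spread)
            else:
                theta = rng.uniform(0.0, math.pi)
            if spec.overlap:
                break
            if all((cy - py) ** 2 + (cx - px) ** 2 > (a + pr) ** 2 for py, px, pr in placed):
                break
        else:
            raise PackingError(
                f"could not place particle {len(placed) + 1} without overlap "
                f"after {max_retries} retries"
            )
        placed.append((cy, cx, a))
        # render on a local patch only
        r = int(math.ceil(a)) + 2
        r0, r1 = max(0, int(cy) - r), min(rows, int(cy) + r + 1)
        c0, c1 = max(0, int(cx) - r), min(cols, int(cx) + r + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dy = yy - cy
        dx = xx - cx
        ct, st = math.cos(theta), math.sin(theta)
        u = (dx * ct + dy * st) / a  # along major axis
        v = (-dx * st + dy * ct) / b
        rho = np.sqrt(u * u + v * v)
        # ~1 px anti-aliasing ramp at the ellipse boundary
        edge = 1.0 / max(1.0, min(a, b))
        coverage = np.clip((1.0 - rho) / edge + 0.5, 0.0, 1.0)
        shade = 1.0 + spec.shading * u  # linear ramp across the grain
        value = np.clip(spec.foreground * shade, 0.0, 1.0)
        patch = img[r0:r1, c0:c1]
        img[r0:r1, c0:c1] = patch * (1.0 - coverage) + coverage * value
    if spec.noise > 0:
        img = img + rng.normal(0.0, spec.noise, size=spec.shape)
    return np.clip(img, 0.0, 1.0)


@dataclass(frozen=True)
class SSDatasetSpec:
    """Two Gaussian classes with means +/- separation * 1-vector, cov scale**2 * I."""

    n_per_class: int = 200
    k: int = 4
    separation: float = 0.8
    covariance_scale: float = 1.0
    label_rate: float = 0.45
    groups: tuple[int, ...] | None = None  # optional split of the unlabeled pool
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.label_rate <= 1):
            raise InvalidParameterError("label_rate must be in (0, 1]")
        n_lab = round(self.label_rate * self.n_per_class)
        if n_lab < self.k + 2:
            raise InvalidParameterError(
                f"label_rate*n per class ({n_lab}) must be >= k+2 ({self.k + 2}) "
                "for TPSRC solvability"
            )


def generate_ss_dataset(spec: SSDatasetSpec):
    """Return (LabeledSet, UnlabeledSet, truth) for a semi-supervised benchmark.

    Exactly round(label_rate * n_per_class) samples per class are labeled. ``truth``
    is a dict with the hidden labels (and optional group ids) of the unlabeled pool.
    """
    rng = np.random.default_rng(spec.seed)
    mean = spec.separation * np.ones(spec.k)
    X_neg = rng.normal(-mean, spec.covariance_scale, size=(spec.n_per_class, spec.k))
    X_pos = rng.normal(mean, spec.covariance_scale, size=(spec.n_per_class, spec.k))
    n_lab = round(spec.label_rate * spec.n_per_class)

    lab_X = np.vstack([X_neg[:n_lab], X_pos[:n_lab]])
    lab_y = np.concatenate([-np.ones(n_lab), np.ones(n_lab)])
    unl_X = np.vstack([X_neg[n_lab:], X_pos[n_lab:]])
    unl_y = np.concatenate(
        [-np.ones(spec.n_per_class - n_lab), np.ones(spec.n_per_class - n_lab)]
    )
    perm = rng.permutation(unl_X.shape[0])
    unl_X, unl_y = unl_X[perm], unl_y[perm]

    truth: dict = {"labels": unl_y}
    if spec.groups is not None:
        if sum(spec.groups) != unl_X.shape[0]:
            raise InvalidParameterError(
                f"group sizes sum to {sum(spec.groups)}, unlabeled pool has {unl_X.shape[0]}"
            )
        gid = np.concatenate(
            [np.full(sz, gi, dtype=int) for gi, sz in enumerate(spec.groups)]
        )
        truth["group_ids"] = gid
    return LabeledSet(lab_X, lab_y), UnlabeledSet(unl_X), truth
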