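"""Omnidirectional multi-scale Weibull texture features of a grain image.

For each steerable template, scale sigma and orientation theta_j = (j-1)*pi/N the
oriented filter response is computed by steering (one set of base convolutions per
scale serves all directions), the integral-form Weibull law is fitted to its interior
pixels, and the triple (mu, beta, lambda) is emitted. Triples are concatenated
directions-fastest into a per-scale block, per-scale blocks into a multi-scale block,
and the global block is followed by one block per subimage of a non-overlapping grid,
giving |scales| * n_directions * 3 * (grid_cells + 1) values per template.

The image is filtered once per scale and the oriented responses are *partitioned*
into the grid for the local blocks; per-region fits use the pixels of the region
intersected with the global interior margin (kernel half-width) so boundary
artifacts never enter the statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import steerable
from .errors import DegenerateInputError, ImageSizeError, LayoutMismatchError
from .steerable import SteerableTemplate, get_template, kernel_half_width
from .weibull import FitOptions, WDParams, fit_wd_mle

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "directional_features",
    "multiscale_features",
    "extended_features",
    "extract_features",
    "feature_length",
    "write_feature_table",
    "read_feature_table",
]

DEFAULT_SCALES = (0.5, math.sqrt(2.0) / 2.0, 1.0, math.sqrt(2.0), 2.0)
_MIN_FIT_PIXELS = 64
PARAM_ORDER = ("mu", "beta", "lam")


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings; defaults follow the standard grading configuration
    (60 directions, five geometric scales at ratio sqrt(2), a 2x2 subimage grid)."""

    template_names: tuple[str, ...] = ("T1", "T2", "T3", "T4", "T5", "T6")
    n_directions: int = 60
    scales: tuple[float, ...] = DEFAULT_SCALES
    subimage_grid: tuple[int, int] = (2, 2)
    truncation: float = 4.0
    phi: float = math.pi / 2.0
    radical_constants: bool = False
    warm_start: bool = True
    fit_options: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self) -> None:
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be strictly positive")
        if self.subimage_grid[0] < 1 or self.subimage_grid[1] < 1:
            raise ValueError("grid dims must be >= 1")

    @property
    def grid_cells(self) -> int:
        return self.subimage_grid[0] * self.subimage_grid[1]

    def templates(self) -> tuple[SteerableTemplate, ...]:
        return tuple(
            get_template(n, phi=self.phi, radical_constants=self.radical_constants)
            for n in self.template_names
        )

    def to_dict(self) -> dict:
        return {
            "template_names": list(self.template_names),
            "n_directions": self.n_directions,
            "scales": list(self.scales),
            "subimage_grid": list(self.subimage_grid),
            "truncation": self.truncation,
            "phi": self.phi,
            "radical_constants": self.radical_constants,
            "warm_start": self.warm_start,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        for key in ("template_names", "scales", "subimage_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered values with an explicit (template, region, scale, direction, param) layout."""

    values: np.ndarray
    layout: tuple[tuple[str, str, float, int, str], ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.layout):
            raise LayoutMismatchError("values and layout length differ")

    def column_names(self) -> list[str]:
        return [layout_entry_name(e) for e in self.layout]


def layout_entry_name(entry: tuple[str, str, float, int, str]) -> str:
    template, region, scale, direction, param = entry
    return f"{template}|{region}|s{scale:.6g}|d{direction:02d}|{param}"


def feature_length(config: FeatureConfig) -> int:
    """len = sum over templates of |scales| * n_directions * 3 * (grid_cells + 1)."""
    per_template = len(config.scales) * config.n_directions * 3 * (config.grid_cells + 1)
    return per_template * len(config.template_names)


def region_names(config: FeatureConfig) -> list[str]:
    return ["global"] + [f"sub{i}" for i in range(config.grid_cells)]


def _grid_blocks(shape: tuple[int, int], grid: tuple[int, int]):
    """Contiguous equal blocks in raster order; remainder pixels join the last block."""
    rows, cols = shape
    gr, gc = grid
    rstep, cstep = rows // gr, cols // gc
    blocks = []
    for i in range(gr):
        r0 = i * rstep
        r1 = rows if i == gr - 1 else (i + 1) * rstep
        for j in range(gc):
            c0 = j * cstep
            c1 = cols if j == gc - 1 else (j + 1) * cstep
            blocks.append((slice(r0, r1), slice(c0, c1)))
    return blocks


def _fit_triple(values: np.ndarray, fit_options: FitOptions, context: str) -> WDParams:
    flat = values.ravel()
    if flat.size < _MIN_FIT_PIXELS:
        raise ImageSizeError(
            f"{context}: only {flat.size} interior pixels, need >= {_MIN_FIT_PIXELS}"
        )
    if float(np.std(flat)) == 0.0:
        raise DegenerateInputError(f"{context}: constant filter response")
    return fit_wd_mle(flat, fit_options).params


def _extract_regions(
    image: np.ndarray,
    template: SteerableTemplate,
    config: FeatureConfig,
    regions: list[tuple[slice, slice] | None],
) -> np.ndarray:
    """(n_regions, n_scales, n_directions, 3) array of fitted triples.

    regions entries are grid slices, or None for the global image.
    """
    image = np.asarray(image, dtype=float)
    thetas = [j * math.pi / config.n_directions for j in range(config.n_directions)]
    out = np.empty((len(regions), len(config.scales), config.n_directions, 3))
    gof_opts = replace(config.fit_options, compute_gof=False)
    for si, sigma in enumerate(config.scales):
        base = steerable.base_responses(image, template, sigma, config.truncation)
        margin = kernel_half_width(sigma, config.truncation)
        if 2 * margin >= min(image.shape):
            raise ImageSizeError(
                f"image {image.shape} has no interior at sigma={sigma} "
                f"(margin {margin})"
            )
        interior = np.zeros(image.shape, dtype=bool)
        interior[margin:-margin, margin:-margin] = True
        warm: list[WDParams | None] = [None] * len(regions)
        for di, theta in enumerate(thetas):
            resp = steerable.oriented_response(
                image, template, sigma, theta, base=base
            ).values
            for ri, reg in enumerate(regions):
                if reg is None:
                    vals = resp[margin:-margin, margin:-margin]
                else:
                    vals = resp[reg][interior[reg]]
                context = (
                    f"template {template.name}, sigma={sigma:g}, theta={theta:.4f}, "
                    f"region {'global' if reg is None else ri - 1}"
                )
                opts = gof_opts
                if config.warm_start and warm[ri] is not None:
                    opts = replace(gof_opts, init=warm[ri])
                params = _fit_triple(np.asarray(vals), opts, context)
                warm[ri] = params
                out[ri, si, di] = (params.mu, params.beta, params.lam)
    return out


def directional_features(
    image: np.ndarray,
    template: SteerableTemplate,
    sigma: float,
    n_directions: int,
    fit_options: FitOptions | None = None,
    truncation: float = 4.0,
    warm_start: bool = True,
) -> np.ndarray:
    """(mu, beta, lam) per direction theta_j = (j-1)*pi/N, concatenated; length 3N."""
    cfg = FeatureConfig(
        template_names=(template.name,),
        n_directions=n_directions,
        scales=(sigma,),
        subimage_grid=(1, 1),
        truncation=truncation,
        warm_start=warm_start,
        fit_options=fit_options or FitOptions(),
    )
    triples = _extract_regions(image, template, cfg, [None])
    return triples[0, 0].ravel()


def multiscale_features(
    image: np.ndarray,
    template: SteerableTemplate,
    config: FeatureConfig,
) -> np.ndarray:
    """Concatenation of directional feature blocks over config.scales, in order."""
    triples = _extract_regions(image, template, config, [None])
    return triples[0].ravel()


def extended_features(
    image: np.ndarray,
    template: SteerableTemplate,
    config: FeatureConfig,
    source_id: str = "",
) -> FeatureVector:
    """Global multi-scale block followed by one block per subimage of the grid."""
    image = np.asarray(image, dtype=float)
    regions: list = [None]
    regions.extend(_grid_blocks(image.shape, config.subimage_grid))
    triples = _extract_regions(image, template, config, regions)
    values = triples.ravel()
    layout = []
    for ri, rname in enumerate(["global"] + [f"sub{i}" for i in range(len(regions) - 1)]):
        for sigma in config.scales:
            for di in range(config.n_directions):
                for p in PARAM_ORDER:
                    layout.append((template.name, rname, float(sigma), di, p))
    return FeatureVector(values=values, layout=tuple(layout), source_id=source_id)


def extract_features(
    image: np.ndarray, config: FeatureConfig, source_id: str = ""
) -> FeatureVector:
    """Extended features for every template in the config, concatenated."""
    parts = [
        extended_features(image, t, config, source_id) for t in config.templates()
    ]
    values = np.concatenate([p.values for p in parts])
    layout = tuple(e for p in parts for e in p.layout)
    fv = FeatureVector(values=values, layout=layout, source_id=source_id)
    assert len(fv.values) == feature_length(config), "dimensional contract violated"
    return fv


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(path, vectors: list[FeatureVector], config: FeatureConfig) -> None:
    """One row per image; a sidecar JSON records the exact extraction config."""
    if not vectors:
        raise ValueError("no feature vectors to write")
    cols = vectors[0].column_names()
    for v in vectors[1:]:
        if v.column_names() != cols:
            raise LayoutMismatchError("feature vectors have inconsistent layouts")
    df = pd.DataFrame(
        [v.values for v in vectors],
        columns=cols,
        index=pd.Index([v.source_id for v in vectors], name="source_id"),
    )
    df.to_csv(path)
    with open(str(path) + ".json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)


def read_feature_table(path, config: FeatureConfig | None = None) -> pd.DataFrame:
    """Read a feature CSV; if a config is given, validate the header against it."""
    df = pd.read_csv(path, index_col="source_id")
    if config is not None:
        expected = []
        for tname in config.template_names:
            for rname in region_names(config)[: config.grid_cells + 1]:
                for sigma in config.scales:
                    for di in range(config.n_directions):
                        for p in PARAM_ORDER:
                            expected.append(
                                layout_entry_name((tname, rname, float(sigma), di, p))
                            )
        if list(df.columns) != expected:
            raise LayoutMismatchError(
                f"feature table header does not match config "
                f"({len(df.columns)} columns, expected {len(expected)})"
            )
    return df
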