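"""End-to-end orchestration: extract -> train -> predict -> evaluate.

Feature columns are standardized (centered/scaled with labeled-set statistics stored
in the model file) before classifier training: thin-plate radial distances across
location/scale/shape columns of very different magnitudes would otherwise be
dominated by the widest columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifiers import LabeledSet
from .cosc import COSCConfig, COSCModel, UnlabeledSet, ce_metrics, cosc_fit, ensemble_predict
from .errors import DegenerateInputError, GraintexError, ImageSizeError, LayoutMismatchError
from .features import FeatureConfig, extract_features, write_feature_table

__all__ = [
    "RunConfig",
    "Standardizer",
    "run_extract",
    "run_train_eval",
    "run_predict",
    "load_image",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration; round-trips YAML -> object -> YAML losslessly."""

    feature: FeatureConfig = field(default_factory=FeatureConfig)
    cosc: COSCConfig = field(default_factory=COSCConfig)
    seed: int = 0
    standardize: bool = True

    def to_dict(self) -> dict:
        cosc = asdict(self.cosc)
        return {
            "feature": self.feature.to_dict(),
            "cosc": cosc,
            "seed": self.seed,
            "standardize": self.standardize,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        feature = FeatureConfig.from_dict(d.get("feature", {}))
        cosc = COSCConfig(**d.get("cosc", {}))
        return cls(
            feature=feature,
            cosc=cosc,
            seed=int(d.get("seed", 0)),
            standardize=bool(d.get("standardize", True)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


@dataclass(frozen=True)
class Standardizer:
    """Per-column centering/scaling learned from the labeled set."""

    means: np.ndarray
    stds: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        means = X.mean(axis=0)
        stds = X.std(axis=0)
        stds = np.where(stds > 0, stds, 1.0)
        return cls(means=means, stds=stds)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.stds

    def to_dict(self) -> dict:
        return {"means": self.means.tolist(), "stds": self.stds.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(np.asarray(d["means"], dtype=float), np.asarray(d["stds"], dtype=float))


def load_image(path) -> np.ndarray:
    """Read a grayscale image and rescale 8/16-bit integers to [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse any color planes
        arr = arr.mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def run_extract(image_paths, config: RunConfig, out_path=None):
    """Extract one feature row per image; unreadable/degenerate images are skipped.

    Returns the DataFrame of successful rows; raises if every image fails.
    """
    vectors = []
    for p in image_paths:
        try:
            img = load_image(p)
            fv = extract_features(img, config.feature, source_id=str(p))
            vectors.append(fv)
        except (OSError, RuntimeError, ValueError, ImageSizeError, DegenerateInputError) as exc:
            # imageio delegates to per-format plugins whose failure types vary
            logger.warning("skipping %s: %s", p, exc)
    if not vectors:
        raise GraintexError("feature extraction failed for every input image")
    df = pd.DataFrame(
        [v.values for v in vectors],
        columns=vectors[0].column_names(),
        index=pd.Index([v.source_id for v in vectors], name="source_id"),
    )
    if out_path is not None:
        write_feature_table(out_path, vectors, config.feature)
    return df


def _check_layout(labeled: pd.DataFrame, unlabeled: pd.DataFrame) -> None:
    if list(labeled.columns) != list(unlabeled.columns):
        extra = set(labeled.columns) ^ set(unlabeled.columns)
        raise LayoutMismatchError(
            f"labeled/unlabeled feature layouts differ; mismatching columns: {sorted(extra)[:6]}"
        )


def run_train_eval(
    labeled_df: pd.DataFrame,
    labels: np.ndarray,
    unlabeled_df: pd.DataFrame,
    config: RunConfig,
    truth: np.ndarray | None = None,
    group_ids=None,
):
    """Train COSC-Boosting on feature tables; report CE/ACE against held-back truth.

    The improvement entry is (initial-ensemble CE - final CE): the gain over the
    plain average of the two classifiers trained on the labeled set alone.
    """
    _check_layout(labeled_df, unlabeled_df)
    X_lab = labeled_df.to_numpy(dtype=float)
    X_unl = unlabeled_df.to_numpy(dtype=float)
    std = Standardizer.fit(X_lab) if config.standardize else None
    if std is not None:
        X_lab, X_unl = std.transform(X_lab), std.transform(X_unl)
    L = LabeledSet(X_lab, np.asarray(labels, dtype=float))
    U = UnlabeledSet(X_unl)

    initial = cosc_fit(L, UnlabeledSet(X_unl[:0]), config.cosc)
    final = cosc_fit(L, U, config.cosc)

    report: dict = {"n_labeled": L.n, "n_unlabeled": U.m, "iterations": len(final.history)}
    if truth is not None and U.m:
        _, init_rv, init_ts = ce_metrics(
            ensemble_predict(initial, X_unl)[1], truth, group_ids
        )
        per_group, fin_rv, fin_ts = ce_metrics(
            ensemble_predict(final, X_unl)[1], truth, group_ids
        )
        report.update(
            {
                "initial_ace_ts": init_ts,
                "final_ace_ts": fin_ts,
                "initial_ace_rv": init_rv,
                "final_ace_rv": fin_rv,
                "improvement_ts": init_ts - fin_ts,
                "per_group_ce": {str(k): v for k, v in per_group.items()},
            }
        )
    return final, std, report


def run_predict(model: COSCModel, std: Standardizer | None, features_df: pd.DataFrame):
    X = features_df.to_numpy(dtype=float)
    if std is not None:
        X = std.transform(X)
    scores, labels = ensemble_predict(model, X)
    return pd.DataFrame(
        {"score": scores, "label": labels}, index=features_df.index
    )


def save_model(path, model: COSCModel, std: Standardizer | None, config: RunConfig) -> None:
    """Model JSON embeds the full run config so any run is reproducible from it."""
    payload = {
        "model": model.to_dict(),
        "standardizer": std.to_dict() if std is not None else None,
        "config": config.to_dict(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    payload = json.loads(Path(path).read_text())
    model = COSCModel.from_dict(payload["model"])
    std = (
        Standardizer.from_dict(payload["standardizer"])
        if payload.get("standardizer")
        else None
    )
    config = RunConfig.from_dict(payload.get("config", {}))
    return model, std, config
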