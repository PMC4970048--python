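"""COSC-Boosting: co-training of TPSRC and MARSC with scarce labels.

Each round draws a pool of M' unlabeled samples with replacement. A pool sample is a
candidate when both classifiers assign it the same thresholded label; its labeling
confidence for a classifier is the decrease of squared error on that classifier's
labeled set when the classifier is refit with the candidate appended. Candidates need
non-negative confidence for *both* classifiers; the per-classifier confidence
maximizer then augments the other classifier's labeled set (cross-teaching). The
final predictor averages the two classifier scores and thresholds at zero. With no
unlabeled data the procedure degenerates to a plain two-classifier ensemble.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .classifiers import (
    LabeledSet,
    MARSCModel,
    TPSRCModel,
    marsc_fit,
    marsc_predict,
    threshold_label,
    tpsrc_fit,
    tpsrc_predict,
)
from .errors import InvalidParameterError

__all__ = [
    "UnlabeledSet",
    "COSCConfig",
    "COSCModel",
    "labeling_confidence",
    "cosc_fit",
    "ensemble_predict",
    "ce_metrics",
]


@dataclass(frozen=True)
class UnlabeledSet:
    features: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        if X.size and (X.ndim != 2 or not np.all(np.isfinite(X))):
            raise InvalidParameterError("unlabeled features must be a finite m x k array")
        object.__setattr__(self, "features", X if X.size else X.reshape(0, X.shape[-1] if X.ndim == 2 else 0))

    @property
    def m(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class COSCConfig:
    """Co-training loop settings.

    ``pool_size`` (M') is the number of unlabeled samples drawn with replacement
    per round. ``cross_teaching=False`` reproduces the literal pseudocode variant
    in which the TPSRC pick augments both labeled sets. ``remove_accepted``
    withdraws virtually labeled samples from the unlabeled reservoir so later
    rounds cannot re-accept them. ``soft_virtual_labels`` appends each accepted
    sample with the teaching classifier's raw regression score (the pseudocode's
    ``y <- h(x)``); switching it off appends the thresholded +/-1 label instead.
    ``tpsrc_eta`` defaults to a strong smoothing: the squared-error confidence
    rule is degenerate for a near-interpolating spline (refits barely move at
    the labeled points), so the spline must be regularized for co-training to
    carry information.
    """

    max_iterations: int = 10
    pool_size: int = 100
    threshold: float = 0.0
    seed: int = 0
    cross_teaching: bool = True
    remove_accepted: bool = True
    soft_virtual_labels: bool = True
    tpsrc_eta: float | str = 10.0
    marsc_max_terms: int | None = None
    marsc_max_degree: int = 2
    marsc_d: float = 3.0

    def __post_init__(self) -> None:
        if self.max_iterations < 1 or self.pool_size < 1:
            raise InvalidParameterError("max_iterations and pool_size must be >= 1")


@dataclass
class COSCModel:
    tpsrc: TPSRCModel
    marsc: MARSCModel
    augmented_L1: LabeledSet
    augmented_L2: LabeledSet
    history: list[dict] = field(default_factory=list)
    threshold: float = 0.0

    def to_dict(self) -> dict:
        return {
            "kind": "cosc",
            "threshold": self.threshold,
            "tpsrc": self.tpsrc.to_dict(),
            "marsc": self.marsc.to_dict(),
            "augmented_L1": {
                "features": self.augmented_L1.features.tolist(),
                "labels": self.augmented_L1.labels.tolist(),
            },
            "augmented_L2": {
                "features": self.augmented_L2.features.tolist(),
                "labels": self.augmented_L2.labels.tolist(),
            },
            "history": self.history,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "COSCModel":
        return cls(
            tpsrc=TPSRCModel.from_dict(d["tpsrc"]),
            marsc=MARSCModel.from_dict(d["marsc"]),
            augmented_L1=LabeledSet(
                np.asarray(d["augmented_L1"]["features"], dtype=float),
                np.asarray(d["augmented_L1"]["labels"], dtype=float),
                soft=True,
            ),
            augmented_L2=LabeledSet(
                np.asarray(d["augmented_L2"]["features"], dtype=float),
                np.asarray(d["augmented_L2"]["labels"], dtype=float),
                soft=True,
            ),
            history=list(d.get("history", [])),
            threshold=float(d.get("threshold", 0.0)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "COSCModel":
        return cls.from_dict(json.loads(text))


class Confidence(NamedTuple):
    """Total squared-error decrease on the labeled set and its per-sample mean."""

    total: float
    normalized: float


def labeling_confidence(scores_current, scores_refined, labeled: LabeledSet) -> Confidence:
    """MSE decrease of a refinement on the labeled set.

    total = sum_i [(y_i - h(x_i))^2 - (y_i - h*(x_i))^2]; positive iff the refined
    classifier is more consistent with the labeled data. ``normalized`` divides by
    the labeled-set size (sign-identical).
    """
    y = labeled.labels
    cur = np.asarray(scores_current, dtype=float)
    ref = np.asarray(scores_refined, dtype=float)
    total = float(np.sum((y - cur) ** 2 - (y - ref) ** 2))
    return Confidence(total=total, normalized=total / labeled.n)


def _fit_pair(L1: LabeledSet, L2: LabeledSet, cfg: COSCConfig):
    h1 = tpsrc_fit(L1, eta=cfg.tpsrc_eta)
    h2 = marsc_fit(
        L2, max_terms=cfg.marsc_max_terms, max_degree=cfg.marsc_max_degree, d=cfg.marsc_d
    )
    return h1, h2


def cosc_fit(L: LabeledSet, U: UnlabeledSet, config: COSCConfig | None = None) -> COSCModel:
    """Run the co-training loop and return the fitted ensemble with its audit history.

    Per iteration at most one virtual sample joins each labeled set; the original
    labels are never overwritten. Stops early when neither labeled set changed.
    """
    cfg = config or COSCConfig()
    if len(np.unique(np.sign(L.labels))) < 2:
        raise InvalidParameterError("labeled set must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    L1 = L2 = LabeledSet(L.features, L.labels, soft=cfg.soft_virtual_labels)
    h1, h2 = _fit_pair(L1, L2, cfg)
    history: list[dict] = []
    if U.m == 0:
        return COSCModel(h1, h2, L1, L2, history, cfg.threshold)

    available = list(range(U.m))
    for it in range(cfg.max_iterations):
        if not available:
            break
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pool_rng = np.random.default_rng(sub_seed)
        pool = pool_rng.choice(available, size=cfg.pool_size, replace=True)
        scores1_L1 = tpsrc_predict(h1, L1.features)
        scores2_L2 = marsc_predict(h2, L2.features)

        candidates = []  # (pool_pos, sample_idx, y1, y2, agreed_label, conf1, conf2)
        seen: dict[int, tuple | None] = {}
        n_agree = 0
        for pos, idx in enumerate(pool):
            idx = int(idx)
            if idx in seen:
                cached = seen[idx]
                if cached is not None:
                    candidates.append((pos, idx, *cached))
                continue
            x = U.features[idx]
            s1 = tpsrc_predict(h1, x)
            s2 = marsc_predict(h2, x)
            lab1 = threshold_label(s1, cfg.threshold)
            lab2 = threshold_label(s2, cfg.threshold)
            if lab1 != lab2:
                seen[idx] = None
                continue
            n_agree += 1
            # virtual target each classifier would append for itself
            y1 = float(s1) if cfg.soft_virtual_labels else float(lab1)
            y2 = float(s2) if cfg.soft_virtual_labels else float(lab2)
            h1_ref = tpsrc_fit(L1.with_sample(x, y1), eta=cfg.tpsrc_eta)
            conf1 = labeling_confidence(
                scores1_L1, tpsrc_predict(h1_ref, L1.features), L1
            )
            if conf1.total < 0:
                seen[idx] = None
                continue
            h2_ref = marsc_fit(
                L2.with_sample(x, y2),
                max_terms=cfg.marsc_max_terms,
                max_degree=cfg.marsc_max_degree,
                d=cfg.marsc_d,
            )
            conf2 = labeling_confidence(
                scores2_L2, marsc_predict(h2_ref, L2.features), L2
            )
            if conf2.total < 0:
                seen[idx] = None
                continue
            seen[idx] = (y1, y2, float(lab1), conf1.total, conf2.total)
            candidates.append((pos, idx, y1, y2, float(lab1), conf1.total, conf2.total))

        pick_tpsrc = pick_marsc = None
        if candidates:
            # ties on confidence resolve to the lowest pool position
            pick_tpsrc = max(candidates, key=lambda c: (c[5], -c[0]))
            pick_marsc = max(candidates, key=lambda c: (c[6], -c[0]))

        added = []
        if pick_tpsrc is not None:
            if cfg.cross_teaching:
                # each classifier labels for the other: MARSC's pick (with
                # MARSC's target) joins TPSRC's set and vice versa
                L1 = L1.with_sample(U.features[pick_marsc[1]], pick_marsc[3])
                L2 = L2.with_sample(U.features[pick_tpsrc[1]], pick_tpsrc[2])
                added = sorted({pick_marsc[1], pick_tpsrc[1]})
            else:
                L1 = L1.with_sample(U.features[pick_tpsrc[1]], pick_tpsrc[2])
                L2 = L2.with_sample(U.features[pick_tpsrc[1]], pick_tpsrc[2])
                added = [pick_tpsrc[1]]

        history.append(
            {
                "iteration": it,
                "sub_seed": sub_seed,
                "pool": [int(i) for i in pool],
                "n_agree": n_agree,
                "candidates": [
                    {
                        "pool_pos": int(p),
                        "index": int(i),
                        "target_tpsrc": ya,
                        "target_marsc": yb,
                        "label": lab,
                        "conf_tpsrc": c1,
                        "conf_marsc": c2,
                    }
                    for (p, i, ya, yb, lab, c1, c2) in candidates
                ],
                "accepted_tpsrc_pick": int(pick_tpsrc[1]) if pick_tpsrc else None,
                "accepted_marsc_pick": int(pick_marsc[1]) if pick_marsc else None,
                "n_L1": L1.n,
                "n_L2": L2.n,
                "stopped_early": not added,
            }
        )
        if not added:
            break
        h1, h2 = _fit_pair(L1, L2, cfg)
        if cfg.remove_accepted:
            available = [i for i in available if i not in added]

    return COSCModel(h1, h2, L1, L2, history, cfg.threshold)


def ensemble_predict(model: COSCModel, X: np.ndarray):
    """Average the two base scores; labels by thresholding at model.threshold."""
    s1 = tpsrc_predict(model.tpsrc, X)
    s2 = marsc_predict(model.marsc, X)
    scores = 0.5 * (np.asarray(s1) + np.asarray(s2))
    labels = threshold_label(scores, model.threshold)
    if np.asarray(X).ndim == 1:
        return float(scores), int(labels)
    return scores, labels


def ce_metrics(pred_labels, true_labels, group_ids=None):
    """Per-group classification error and the two averaged errors, in percent.

    CE_i = mean(|yhat - y| / 2) * 100 over group i; ACE_RV is the unweighted mean
    of the group CEs (one value per product variety); ACE_TS pools all samples.
    Empty groups are excluded.
    """
    yhat = np.asarray(pred_labels, dtype=float)
    y = np.asarray(true_labels, dtype=float)
    if yhat.shape != y.shape:
        raise InvalidParameterError("prediction/truth length mismatch")
    if group_ids is None:
        group_ids = np.zeros(y.shape[0], dtype=int)
    groups = np.asarray(group_ids)
    err = np.abs(yhat - y) / 2.0
    per_group: dict = {}
    for g in np.unique(groups):
        mask = groups == g
        if not np.any(mask):
            continue
        per_group[g.item() if hasattr(g, "item") else g] = float(err[mask].mean() * 100.0)
    ace_rv = float(np.mean(list(per_group.values())))
    ace_ts = float(err.mean() * 100.0)
    return per_group, ace_rv, ace_ts
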