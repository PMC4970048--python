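"""The two complementary supervised learners behind the co-training loop.

TPSRC — thin-plate-spline regression classifier: penalized radial-basis regression
of the +/-1 labels with Green's function phi(r) = r^2 log r, solved through the
standard augmented linear system with polynomial side conditions. It reads each
feature vector as a whole (responses depend on distances ||x - x_j||), ignoring
per-coordinate structure.

MARSC — multivariate adaptive regression splines classifier: an adaptive expansion
in products of hinge functions [s*(x_v - t)]_+ grown by a greedy forward pass and
pruned backward under generalized cross-validation (GCV). It exploits individual
coordinates and their interactions — the complement of TPSRC.

Both produce a real-valued score thresholded into {-1, +1} ("high quality" = -1,
score <= T).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "LabeledSet",
    "TPSRCModel",
    "MARSCModel",
    "BasisFunction",
    "tpsrc_fit",
    "tpsrc_predict",
    "marsc_fit",
    "mars_regress",
    "marsc_predict",
    "gcv",
    "threshold_label",
]

logger = logging.getLogger(__name__)

DEFAULT_ETA_GRID = tuple(float(v) for v in np.logspace(-6, 2, 9))


@dataclass(frozen=True)
class LabeledSet:
    """n feature vectors with labels in {-1, +1}; -1 encodes "high quality".

    ``soft=True`` admits real-valued targets: the co-training loop appends
    virtually labeled samples carrying the raw regression score of the teaching
    classifier rather than a thresholded class label.
    """

    features: np.ndarray
    labels: np.ndarray
    soft: bool = False

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise InvalidParameterError("features must be n x k with n labels")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise InvalidParameterError("missing/non-finite values are not allowed")
        if not self.soft and not np.all(np.isin(y, (-1.0, 1.0))):
            raise InvalidParameterError("labels must be -1 or +1")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def k(self) -> int:
        return self.features.shape[1]

    def with_sample(self, x: np.ndarray, y: float, soft: bool | None = None) -> "LabeledSet":
        return LabeledSet(
            np.vstack([self.features, np.asarray(x, dtype=float)[None, :]]),
            np.append(self.labels, float(y)),
            soft=self.soft if soft is None else soft,
        )


def threshold_label(score: float, T: float = 0.0):
    """-1 ("high quality") if score <= T else +1; boundary goes to -1."""
    s = np.asarray(score, dtype=float)
    out = np.where(s <= T, -1, 1)
    return int(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# TPSRC
# ---------------------------------------------------------------------------

def _tps_green(r: np.ndarray) -> np.ndarray:
    """phi(r) = r^2 log r with the removable singularity phi(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r * r * np.log(r)
    return np.where(r > 0, out, 0.0)


@dataclass(frozen=True)
class TPSRCModel:
    omega0: float
    omega: np.ndarray
    psi: np.ndarray
    anchors: np.ndarray
    eta: float

    def to_dict(self) -> dict:
        return {
            "kind": "tpsrc",
            "omega0": self.omega0,
            "omega": np.asarray(self.omega).tolist(),
            "psi": np.asarray(self.psi).tolist(),
            "anchors": np.asarray(self.anchors).tolist(),
            "eta": self.eta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TPSRCModel":
        return cls(
            omega0=float(d["omega0"]),
            omega=np.asarray(d["omega"], dtype=float),
            psi=np.asarray(d["psi"], dtype=float),
            anchors=np.asarray(d["anchors"], dtype=float),
            eta=float(d["eta"]),
        )


def _tpsrc_solve(K: np.ndarray, P: np.ndarray, y: np.ndarray, eta: float):
    n, q = P.shape
    M = np.zeros((n + q, n + q))
    M[:n, :n] = K + eta * np.eye(n)
    M[:n, n:] = P
    M[n:, :n] = P.T
    rhs = np.concatenate([y, np.zeros(q)])
    sol = np.linalg.solve(M, rhs)
    return sol[:n], sol[n:]


def tpsrc_fit(
    data: LabeledSet,
    eta: float | str = "gcv",
    eta_grid: tuple[float, ...] = DEFAULT_ETA_GRID,
) -> TPSRCModel:
    """Solve the thin-plate smoothing system  [[K + eta*I, P], [P', 0]] [psi; w] = [y; 0].

    K_ij = phi(||x_i - x_j||), P = [1 | X]. The side conditions P' psi = 0 make the
    radial part orthogonal to affine functions. ``eta="gcv"`` selects the
    regularization from ``eta_grid`` by generalized cross-validation on the
    training scores; a non-negative float fixes it. A singular system triggers an
    automatic regularization bump with a warning.
    """
    X, y = data.features, data.labels
    n, k = X.shape
    if n < k + 2:
        raise InvalidParameterError(
            f"TPSRC needs n >= k+2 samples (n={n}, k={k}): under-determined"
        )
    diff = X[:, None, :] - X[None, :, :]
    R = np.sqrt(np.sum(diff * diff, axis=-1))
    K = _tps_green(R)
    P = np.hstack([np.ones((n, 1)), X])

    if isinstance(eta, str):
        if eta != "gcv":
            raise InvalidParameterError(f"eta must be a float or 'gcv', got {eta!r}")
        best = None
        for e in eta_grid:
            try:
                score = _tpsrc_gcv_score(K, P, y, e)
            except np.linalg.LinAlgError:
                continue
            if best is None or score < best[0]:
                best = (score, e)
        if best is None:
            raise np.linalg.LinAlgError("TPSRC system singular for every eta in grid")
        eta_val = best[1]
    else:
        eta_val = float(eta)
        if eta_val < 0:
            raise InvalidParameterError("eta must be non-negative")

    bump = eta_val
    for attempt in range(6):
        try:
            psi, w = _tpsrc_solve(K, P, y, bump)
            break
        except np.linalg.LinAlgError:
            bump = max(bump, 1e-10) * 100.0
            logger.warning("TPSRC system singular; bumping eta to %.3g", bump)
    else:
        raise np.linalg.LinAlgError("TPSRC system remained singular after bumps")
    return TPSRCModel(
        omega0=float(w[0]), omega=w[1:].copy(), psi=psi, anchors=X.copy(), eta=bump
    )


def _tpsrc_gcv_score(K: np.ndarray, P: np.ndarray, y: np.ndarray, eta: float) -> float:
    """GCV(eta) = n * RSS / (n - tr A)^2 with A the training-score influence matrix."""
    n, q = P.shape
    M = np.zeros((n + q, n + q))
    M[:n, :n] = K + eta * np.eye(n)
    M[:n, n:] = P
    M[n:, :n] = P.T
    Minv = np.linalg.inv(M)
    A = np.hstack([K, P]) @ Minv[:, :n]
    yhat = A @ y
    rss = float(np.sum((y - yhat) ** 2))
    tra = float(np.trace(A))
    denom = n - tra
    if denom <= 1e-9:
        return float("inf")
    return n * rss / denom**2


def tpsrc_predict(model: TPSRCModel, x: np.ndarray):
    """Score omega0 + omega'x + sum_j psi_j * phi(||x - x_j||); vectorized over rows."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != model.anchors.shape[1]:
        raise InvalidParameterError(
            f"feature length {X.shape[1]} != model dimension {model.anchors.shape[1]}"
        )
    diff = X[:, None, :] - model.anchors[None, :, :]
    R = np.sqrt(np.sum(diff * diff, axis=-1))
    scores = model.omega0 + X @ model.omega + _tps_green(R) @ model.psi
    return float(scores[0]) if np.asarray(x).ndim == 1 else scores


# ---------------------------------------------------------------------------
# MARSC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisFunction:
    """Product of hinge factors (sign, variable index, knot)."""

    factors: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if not self.factors:
            raise InvalidParameterError("basis function needs at least one factor")
        vars_ = [v for (_, v, _) in self.factors]
        if len(set(vars_)) != len(vars_):
            raise InvalidParameterError("factors within a product must use distinct variables")

    @property
    def degree(self) -> int:
        return len(self.factors)

    @property
    def variables(self) -> frozenset[int]:
        return frozenset(v for (_, v, _) in self.factors)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        col = np.ones(X.shape[0])
        for s, v, t in self.factors:
            col = col * np.maximum(0.0, s * (X[:, v] - t))
        return col


@dataclass(frozen=True)
class MARSCModel:
    alpha0: float
    basis: tuple[BasisFunction, ...]
    alphas: np.ndarray
    gcv: float

    def to_dict(self) -> dict:
        return {
            "kind": "marsc",
            "alpha0": self.alpha0,
            "basis": [[list(f) for f in b.factors] for b in self.basis],
            "alphas": np.asarray(self.alphas).tolist(),
            "gcv": self.gcv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MARSCModel":
        basis = tuple(
            BasisFunction(tuple((int(s), int(v), float(t)) for (s, v, t) in b))
            for b in d["basis"]
        )
        return cls(
            alpha0=float(d["alpha0"]),
            basis=basis,
            alphas=np.asarray(d["alphas"], dtype=float),
            gcv=float(d["gcv"]),
        )


def gcv(rss: float, K: int, M: int, d: float = 3.0) -> float:
    """GCV(K) = (rss / M) / (1 - C(K)/M)^2 with complexity C(K) = K*(d/2 + 1).

    Returns +inf when M <= C(K) (the penalty is undefined there).
    """
    if rss < 0:
        raise InvalidParameterError("rss must be non-negative")
    c = K * (d / 2.0 + 1.0)
    if M <= c:
        return float("inf")
    return (rss / M) / (1.0 - c / M) ** 2


def _design_matrix(basis: tuple[BasisFunction, ...], X: np.ndarray) -> np.ndarray:
    cols = [np.ones(X.shape[0])]
    cols.extend(b.evaluate(X) for b in basis)
    return np.column_stack(cols)


def _lstsq_rss(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


def marsc_fit(
    data: LabeledSet,
    max_terms: int | None = None,
    max_degree: int = 2,
    d: float = 3.0,
) -> MARSCModel:
    """Forward/backward stepwise MARS on the +/-1 labels (see ``mars_regress``)."""
    return mars_regress(data.features, data.labels, max_terms, max_degree, d)


def mars_regress(
    X: np.ndarray,
    y: np.ndarray,
    max_terms: int | None = None,
    max_degree: int = 2,
    d: float = 3.0,
    prune: bool = True,
) -> MARSCModel:
    """Forward/backward stepwise MARS regression on an arbitrary real target.

    Forward pass: greedily add reflected hinge pairs (parent basis x new variable
    x observed-value knot) minimizing the least-squares residual, until
    ``max_terms`` basis functions or no improvement. Backward pass: delete basis
    functions one at a time, keeping the subset minimizing GCV. Knot candidates
    are all observed values of the chosen variable where the parent is active.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if max_terms is None:
        max_terms = min(21, n // 2)
    if n <= max_terms:
        raise InvalidParameterError(f"need n > max_terms (n={n}, max_terms={max_terms})")
    if max_degree < 1:
        raise InvalidParameterError("max_degree must be >= 1")

    basis: list[BasisFunction] = []
    B = np.ones((n, 1))
    _, rss = _lstsq_rss(B, y)
    y_var = float(np.sum((y - y.mean()) ** 2))
    rss_floor = max(1e-12, 1e-12 * max(y_var, 1.0))

    while len(basis) < max_terms and rss > rss_floor:
        Q, _ = np.linalg.qr(B)
        r = y - Q @ (Q.T @ y)
        best = None  # (reduction, parent_idx, var, knot)
        parents: list[tuple[int, BasisFunction | None]] = [(0, None)]
        parents.extend((i + 1, b) for i, b in enumerate(basis))
        for pidx, parent in parents:
            pdeg = 0 if parent is None else parent.degree
            if pdeg >= max_degree:
                continue
            pcol = B[:, pidx]
            used = frozenset() if parent is None else parent.variables
            active = pcol != 0
            if not np.any(active):
                continue
            for v in range(k):
                if v in used:
                    continue
                knots = np.unique(X[active, v])
                if knots.size == 0:
                    continue
                red, kidx = _best_knot_reduction(Q, r, pcol, X[:, v], knots)
                if red is None:
                    continue
                if best is None or red > best[0] + 1e-15:
                    best = (red, pidx, v, float(knots[kidx]))
        if best is None or best[0] <= max(1e-10, 1e-10 * y_var):
            break
        red, pidx, v, knot = best
        parent = None if pidx == 0 else basis[pidx - 1]
        new_pair = []
        for sign in (+1, -1):
            factors = ((sign, v, knot),) if parent is None else parent.factors + ((sign, v, knot),)
            bf = BasisFunction(factors)
            col = bf.evaluate(X)
            if float(col @ col) > 1e-20:
                new_pair.append((bf, col))
        if not new_pair:
            break
        for bf, col in new_pair:
            if len(basis) >= max_terms:
                break
            basis.append(bf)
            B = np.column_stack([B, col])
        _, rss = _lstsq_rss(B, y)

    # Backward pruning under GCV: keep the best subset along the deletion path.
    current = list(range(len(basis)))
    coef, rss = _lstsq_rss(_design_matrix(tuple(basis[i] for i in current), X), y)
    best_subset = list(current)
    best_gcv = gcv(rss, len(current), n, d)
    if not prune:
        current = []
    while current:
        trial_best = None
        for drop in current:
            subset = [i for i in current if i != drop]
            _, rss_s = _lstsq_rss(_design_matrix(tuple(basis[i] for i in subset), X), y)
            g = gcv(rss_s, len(subset), n, d)
            if trial_best is None or g < trial_best[0]:
                trial_best = (g, subset)
        current = trial_best[1]
        if trial_best[0] <= best_gcv:
            best_gcv = trial_best[0]
            best_subset = list(current)

    final_basis = tuple(basis[i] for i in best_subset)
    coef, rss = _lstsq_rss(_design_matrix(final_basis, X), y)
    return MARSCModel(
        alpha0=float(coef[0]),
        basis=final_basis,
        alphas=np.asarray(coef[1:], dtype=float),
        gcv=gcv(rss, len(final_basis), n, d),
    )


def _best_knot_reduction(Q, r, pcol, xv, knots):
    """Vectorized RSS reduction of adding the reflected hinge pair at each knot.

    Projects both candidate columns out of the current fitted subspace (Q) and
    solves the per-knot 2x2 normal equations in closed form; falls back to the
    better single column where the pair is numerically collinear.
    """
    Cp = pcol[:, None] * np.maximum(0.0, xv[:, None] - knots[None, :])
    Cm = pcol[:, None] * np.maximum(0.0, knots[None, :] - xv[:, None])
    Cp = Cp - Q @ (Q.T @ Cp)
    Cm = Cm - Q @ (Q.T @ Cm)
    g11 = np.einsum("ij,ij->j", Cp, Cp)
    g22 = np.einsum("ij,ij->j", Cm, Cm)
    g12 = np.einsum("ij,ij->j", Cp, Cm)
    b1 = Cp.T @ r
    b2 = Cm.T @ r
    det = g11 * g22 - g12 * g12
    eps = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        red_pair = (g22 * b1 * b1 - 2.0 * g12 * b1 * b2 + g11 * b2 * b2) / det
        red_p = np.where(g11 > eps, b1 * b1 / np.where(g11 > eps, g11, 1.0), 0.0)
        red_m = np.where(g22 > eps, b2 * b2 / np.where(g22 > eps, g22, 1.0), 0.0)
    ok_pair = det > 1e-10 * np.maximum(g11 * g22, eps)
    red = np.where(ok_pair, red_pair, np.maximum(red_p, red_m))
    red = np.where(np.isfinite(red), red, 0.0)
    if red.size == 0:
        return None, None
    idx = int(np.argmax(red))
    return float(red[idx]), idx


def marsc_predict(model: MARSCModel, x: np.ndarray):
    """alpha0 + sum_i alpha_i * prod_k [s_km (x_{v(k,m)} - t_km)]_+ ; vectorized."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    needed = max((max(v for (_, v, _) in b.factors) for b in model.basis), default=-1)
    if X.shape[1] <= needed:
        raise InvalidParameterError(
            f"feature length {X.shape[1]} too short for model using variable {needed}"
        )
    scores = np.full(X.shape[0], model.alpha0)
    for a, b in zip(model.alphas, model.basis):
        scores = scores + a * b.evaluate(X)
    return float(scores[0]) if np.asarray(x).ndim == 1 else scores
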