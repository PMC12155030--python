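"""Nuisance learners: parametric logistic variants, simple smoothers, and a
cross-validated convex ensemble (super learner).

The ensemble performs V-fold stratified cross-validation, scores every library
member by out-of-fold binomial log-loss, and solves for the convex combination
of member probabilities that minimizes the same cross-validated log-loss.  The
convex minimizer can never do worse than the best single member on the same
folds, which is the property that protects downstream estimators against
committing to a single misspecified regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

__all__ = [
    "LearnerSpec",
    "FittedLearner",
    "fit_learner",
    "DegenerateFitError",
    "main_terms",
    "with_interactions",
    "with_squares",
    "knn_smoother",
    "tree_stumps",
    "saturated",
    "constant_rate",
    "default_ensemble",
]

# Tiny ridge keeps saturated/interaction logistic fits from separating on
# small cells; equivalent penalty strength 1e-6.
_RIDGE_C = 1.0e6
_PRED_EPS = 1.0e-12
_LOSS_EPS = 1.0e-10

SINGLE_KINDS = (
    "logistic_main_terms",
    "logistic_interactions",
    "logistic_squares",
    "knn_smoother",
    "tree_stump_ensemble",
    "saturated",
    "constant",
)


class DegenerateFitError(ValueError):
    """Labels are single-class for a learner that cannot fit them; use the
    ``constant`` learner as a fallback."""


@dataclass(frozen=True)
class LearnerSpec:
    """Declarative description of a learner.

    ``kind`` is one of the single-learner kinds or ``"ensemble"``; for an
    ensemble, ``library`` lists the (non-ensemble) members, ``n_folds`` the
    cross-validation folds, and ``seed`` fixes the fold permutation.
    """

    kind: str
    params: tuple[tuple[str, object], ...] = ()
    library: tuple["LearnerSpec", ...] = ()
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind == "ensemble":
            if not self.library:
                raise ValueError("ensemble library must be non-empty")
            if any(m.kind == "ensemble" for m in self.library):
                raise ValueError("nested ensembles are not allowed")
            if self.n_folds < 2:
                raise ValueError("ensemble needs n_folds >= 2")
        elif self.kind not in SINGLE_KINDS:
            raise ValueError(
                f"unknown learner kind {self.kind!r}; options: "
                f"{', '.join(SINGLE_KINDS + ('ensemble',))}"
            )

    def param(self, name: str, default=None):
        return dict(self.params).get(name, default)


def main_terms() -> LearnerSpec:
    return LearnerSpec("logistic_main_terms")


def with_interactions() -> LearnerSpec:
    """Logistic regression with all pairwise interaction terms."""
    return LearnerSpec("logistic_interactions")


def with_squares() -> LearnerSpec:
    """Main-terms logistic plus squared terms for non-binary columns."""
    return LearnerSpec("logistic_squares")


def knn_smoother(k: int = 50) -> LearnerSpec:
    return LearnerSpec("knn_smoother", params=(("k", k),))


def tree_stumps(n_estimators: int = 100) -> LearnerSpec:
    return LearnerSpec("tree_stump_ensemble", params=(("n_estimators", n_estimators),))


def saturated() -> LearnerSpec:
    """Nonparametric cell means over the discrete feature support."""
    return LearnerSpec("saturated")


def constant_rate() -> LearnerSpec:
    return LearnerSpec("constant")


def default_ensemble(seed: int = 0, n_folds: int = 5) -> LearnerSpec:
    """Default super-learner library: main-terms logistic, pairwise-interaction
    logistic, logistic with squared continuous terms, and a k-NN probability
    smoother."""
    return LearnerSpec(
        "ensemble",
        library=(main_terms(), with_interactions(), with_squares(), knn_smoother()),
        n_folds=n_folds,
        seed=seed,
    )


@dataclass
class FittedLearner:
    """Opaque fitted state with a deterministic probability predictor."""

    spec: LearnerSpec
    columns: tuple[str, ...]
    _predict_fn: Callable[[np.ndarray], np.ndarray]
    weights: Optional[np.ndarray] = None          # ensemble only
    cv_risks: Optional[np.ndarray] = None          # per-member CV log-loss
    cv_risk_ensemble: Optional[float] = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ValueError(f"prediction frame missing columns {missing}")
        arr = X[list(self.columns)].to_numpy(dtype=float)
        p = np.asarray(self._predict_fn(arr), dtype=float)
        return np.clip(p, 0.0, 1.0)


def _log_loss(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _LOSS_EPS, 1.0 - _LOSS_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _validate(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    if X.isna().any().any():
        raise ValueError("features contain missing values")
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("labels contain missing values")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    if len(y) != len(X):
        raise ValueError("features and labels disagree in length")
    return y


def _fit_single(spec: LearnerSpec, arr: np.ndarray, y: np.ndarray) -> Callable:
    kind = spec.kind
    classes = np.unique(y)

    if kind == "constant":
        rate = float(y.mean())
        return lambda Z: np.full(len(Z), rate)

    if kind == "saturated":
        # Empirical mean of y within each distinct feature pattern; unseen
        # patterns fall back to the overall mean.
        keys = [tuple(row) for row in arr]
        sums: dict[tuple, list[float]] = {}
        for key, yi in zip(keys, y):
            s = sums.setdefault(key, [0.0, 0.0])
            s[0] += yi
            s[1] += 1.0
        cells = {k: s[0] / s[1] for k, s in sums.items()}
        overall = float(y.mean())

        def predict(Z: np.ndarray) -> np.ndarray:
            return np.array([cells.get(tuple(row), overall) for row in Z])

        return predict

    if len(classes) < 2:
        raise DegenerateFitError(
            f"labels are single-class ({classes[0]:g}); learner kind {kind!r} "
            "cannot fit them — use the 'constant' learner as a fallback"
        )

    if kind == "logistic_main_terms":
        model = LogisticRegression(C=_RIDGE_C, max_iter=2000)
        model.fit(arr, y)
        return lambda Z: model.predict_proba(Z)[:, 1]

    if kind == "logistic_interactions":
        poly = PolynomialFeatures(degree=2, interaction_only=True, include_bias=False)
        Xp = poly.fit_transform(arr)
        model = LogisticRegression(C=_RIDGE_C, max_iter=2000)
        model.fit(Xp, y)
        return lambda Z: model.predict_proba(poly.transform(Z))[:, 1]

    if kind == "logistic_squares":
        # Square only columns that are not two-valued in training data; a
        # squared binary column duplicates the original.
        sq_cols = [j for j in range(arr.shape[1]) if len(np.unique(arr[:, j])) > 2]

        def design(Z: np.ndarray) -> np.ndarray:
            if not sq_cols:
                return Z
            return np.column_stack([Z] + [Z[:, j] ** 2 for j in sq_cols])

        model = LogisticRegression(C=_RIDGE_C, max_iter=2000)
        model.fit(design(arr), y)
        return lambda Z: model.predict_proba(design(Z))[:, 1]

    if kind == "knn_smoother":
        k = min(int(spec.param("k", 50)), len(y))
        scaler = StandardScaler()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns scale to 0
            Xs = scaler.fit_transform(arr)
        model = KNeighborsClassifier(n_neighbors=k)
        model.fit(Xs, y)
        pos = int(np.where(model.classes_ == 1.0)[0][0])
        return lambda Z: model.predict_proba(scaler.transform(Z))[:, pos]

    if kind == "tree_stump_ensemble":
        model = GradientBoostingClassifier(
            max_depth=1,
            n_estimators=int(spec.param("n_estimators", 100)),
            learning_rate=0.1,
            random_state=spec.seed,
        )
        model.fit(arr, y)
        pos = int(np.where(model.classes_ == 1.0)[0][0])
        return lambda Z: model.predict_proba(Z)[:, pos]

    raise AssertionError(f"unreachable kind {kind!r}")


def _simplex_weights(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Convex weights minimizing log-loss of the blended probability.

    Solved on the probability simplex with SLSQP; if the optimizer returns a
    point worse than the best vertex (a rare numerical event), the best vertex
    is used instead, so ensemble CV risk never exceeds the best member's.
    """
    L = Z.shape[1]
    Zc = np.clip(Z, _LOSS_EPS, 1.0 - _LOSS_EPS)

    def objective(w: np.ndarray) -> float:
        return _log_loss(y, Zc @ w)

    def gradient(w: np.ndarray) -> np.ndarray:
        p = np.clip(Zc @ w, _LOSS_EPS, 1.0 - _LOSS_EPS)
        g = (p - y) / (p * (1.0 - p))
        return Zc.T @ g / len(y)

    x0 = np.full(L, 1.0 / L)
    res = minimize(
        objective,
        x0,
        jac=gradient,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * L,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1.0e-12},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum()

    vertex_losses = [objective(np.eye(L)[j]) for j in range(L)]
    best = int(np.argmin(vertex_losses))
    if objective(w) > vertex_losses[best] + 1.0e-9:
        w = np.eye(L)[best]
    return w


def _fit_ensemble(spec: LearnerSpec, arr: np.ndarray, y: np.ndarray,
                  columns: tuple[str, ...]) -> FittedLearner:
    n = len(y)
    L = len(spec.library)
    n_folds = min(spec.n_folds, int(min(np.bincount(y.astype(int), minlength=2))))
    if n_folds < 2:
        raise DegenerateFitError(
            "too few records in one label class for cross-validation; "
            "use the 'constant' learner as a fallback"
        )
    if n < spec.n_folds:
        raise ValueError(f"fewer records ({n}) than folds ({spec.n_folds})")

    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    Z = np.empty((n, L))
    for train_idx, test_idx in splitter.split(arr, y):
        for j, member in enumerate(spec.library):
            try:
                fn = _fit_single(member, arr[train_idx], y[train_idx])
            except DegenerateFitError:
                rate = float(y[train_idx].mean())
                fn = (lambda r: (lambda M: np.full(len(M), r)))(rate)
            Z[test_idx, j] = np.clip(fn(arr[test_idx]), 0.0, 1.0)

    cv_risks = np.array([_log_loss(y, Z[:, j]) for j in range(L)])
    w = _simplex_weights(Z, y)
    cv_risk_ens = _log_loss(y, np.clip(Z, _LOSS_EPS, 1 - _LOSS_EPS) @ w)

    members = []
    for member in spec.library:
        try:
            members.append(_fit_single(member, arr, y))
        except DegenerateFitError:
            rate = float(y.mean())
            members.append((lambda r: (lambda M: np.full(len(M), r)))(rate))

    def predict(Zq: np.ndarray) -> np.ndarray:
        preds = np.column_stack([np.clip(m(Zq), 0.0, 1.0) for m in members])
        return preds @ w

    return FittedLearner(
        spec=spec,
        columns=columns,
        _predict_fn=predict,
        weights=w,
        cv_risks=cv_risks,
        cv_risk_ensemble=cv_risk_ens,
    )


def fit_learner(spec: LearnerSpec, features: pd.DataFrame, labels) -> FittedLearner:
    """Fit ``spec`` to a feature frame and binary labels.

    For ``kind="ensemble"`` this runs stratified V-fold cross-validation with
    the seed carried on the spec, computes per-member out-of-fold log-loss,
    solves for
    convex blending weights, and refits every member on the full data.
    """
    y = _validate(features, labels)
    columns = tuple(features.columns)
    arr = features.to_numpy(dtype=float)
    if spec.kind == "ensemble":
        return _fit_ensemble(spec, arr, y, columns)
    fn = _fit_single(spec, arr, y)
    return FittedLearner(spec=spec, columns=columns, _predict_fn=fn)
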