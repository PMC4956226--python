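"""Harnesses for the five shock/no-shock classifiers and the single-feature
maximum-likelihood threshold rule.

The optimizers themselves are scikit-learn's; this module owns the contracts
around them: the hyperparameter grids, patient-grouped 10-fold cross
validation (no patient ever straddles folds), out-of-bag model selection for
the bagged ensembles, balanced-error-rate scoring, seed determinism, the +/-1
label convention with ties broken to +1, and feature-attribution vectors
(|w_k| for the L1 logistic regression, impurity importances for the tree
ensembles) that the embedded feature selection consumes.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import MetricSet, MetricUndefinedError, metrics
from .features import FeatureDataset
from .records import NSH, SH

ALGORITHMS = ("L1LR", "BAG", "RF", "BST", "SVM")

#: number of trees for the bagged ensembles; performance is insensitive to
#: this once it is large enough, so it is fixed rather than tuned
N_TREES = 300

DEFAULT_GRIDS: dict[str, dict] = {
    "L1LR": {"lam": np.logspace(-4, 1, 20)},
    "SVM": {"C": np.logspace(-2, 3, 6), "gamma": np.logspace(-3, 1, 5)},
    "BST": {"depth": [1, 2, 3], "M": [100, 300, 500]},
    "BAG": {"depth": [2, 4, 8, None]},
    "RF": {"depth": [2, 4, 8, None]},
}


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice plus an optional grid override for tuning."""

    algorithm: str
    grid: dict | None = None
    n_trees: int = N_TREES

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def effective_grid(self) -> dict:
        return self.grid if self.grid is not None else DEFAULT_GRIDS[self.algorithm]


@dataclass
class TrainedModel:
    """Fitted decision function with attribution and training metadata."""

    spec: ModelSpec
    estimator: object
    feature_names: list[str]
    hyperparams: dict
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def attribution(self) -> np.ndarray | None:
        """Feature-attribution vector (length K); None for SVM."""
        est = self.estimator
        alg = self.spec.algorithm
        if alg == "L1LR":
            return np.abs(est.coef_.ravel())
        if alg in ("RF", "BST"):
            return np.asarray(est.feature_importances_)
        if alg == "BAG":
            return np.mean(
                [t.feature_importances_ for t in est.estimators_], axis=0
            )
        return None

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(X))
        proba = est.predict_proba(X)
        pos = list(est.classes_).index(SH)
        return proba[:, pos] - proba[:, 1 - pos]

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _make_estimator(alg: str, hp: dict, n_trees: int, seed: int):
    if alg == "L1LR":
        return LogisticRegression(
            l1_ratio=1.0, C=1.0 / hp["lam"], solver="liblinear", max_iter=2000,
            random_state=seed,
        )
    if alg == "SVM":
        return SVC(kernel="rbf", C=hp["C"], gamma=hp["gamma"], random_state=seed)
    if alg == "BST":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=hp["depth"]),
            n_estimators=hp["M"],
            random_state=seed,
        )
    if alg == "BAG":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(max_depth=hp["depth"]),
            n_estimators=n_trees,
            random_state=seed,
        )
    if alg == "RF":
        # p = floor(sqrt(K)) features per split, the standard default
        return RandomForestClassifier(
            n_estimators=n_trees, max_depth=hp["depth"], max_features="sqrt",
            random_state=seed,
        )
    raise ValueError(alg)


def _grid_points(grid: dict) -> list[dict]:
    keys = list(grid)
    points: list[dict] = [{}]
    for k in keys:
        points = [dict(p, **{k: v}) for p in points for v in grid[k]]
    return points


def _check_two_classes(y: np.ndarray) -> None:
    if not ((y == SH).any() and (y == NSH).any()):
        raise ValueError("training data must contain both classes")


def _cv_ber(alg, hp, n_trees, X, y, groups, n_folds, seed) -> float:
    """Mean BER over patient-grouped folds.

    Folds whose validation patients miss a class cannot define a BER; when
    every fold is degenerate this way (common when each patient carries a
    single rhythm), the out-of-fold predictions are pooled and scored once
    instead.
    """
    n_groups = np.unique(groups).size
    splitter = GroupKFold(n_splits=min(n_folds, n_groups))
    bers = []
    pooled_y, pooled_pred = [], []
    for tr, va in splitter.split(X, y, groups):
        if not ((y[tr] == SH).any() and (y[tr] == NSH).any()):
            continue
        est = _make_estimator(alg, hp, n_trees, seed)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[va])
        pooled_y.append(y[va])
        pooled_pred.append(pred)
        try:
            bers.append(metrics(y[va], pred).ber)
        except MetricUndefinedError:
            continue
    if bers:
        return float(np.mean(bers))
    if pooled_y:
        try:
            return metrics(np.concatenate(pooled_y), np.concatenate(pooled_pred)).ber
        except MetricUndefinedError:
            pass
    return np.inf


def _oob_ber(alg, hp, n_trees, X, y, seed) -> float:
    """Out-of-bag BER for the bagged ensembles."""
    if alg == "BAG":
        est = BaggingClassifier(
            estimator=DecisionTreeClassifier(max_depth=hp["depth"]),
            n_estimators=n_trees, oob_score=True, random_state=seed,
        )
    else:
        est = RandomForestClassifier(
            n_estimators=n_trees, max_depth=hp["depth"], max_features="sqrt",
            oob_score=True, random_state=seed,
        )
    est.fit(X, y)
    proba = est.oob_decision_function_
    ok = ~np.isnan(proba).any(axis=1)
    pos = list(est.classes_).index(SH)
    pred = np.where(proba[ok, pos] >= 0.5, SH, NSH)
    return metrics(y[ok], pred).ber


def tune(
    spec: ModelSpec,
    train: FeatureDataset,
    seed: int = 0,
    n_folds: int = 10,
) -> dict:
    """Choose hyperparameters on the documented grid.

    L1LR, SVM and BST use patient-grouped cross-validated BER; BAG and RF use
    the out-of-bag misclassification BER.  Deterministic given the seed; ties
    resolve to the first grid point in enumeration order.
    """
    X = train.X.to_numpy()
    y = train.y
    _check_two_classes(y)
    best_hp, best_ber = None, np.inf
    for hp in _grid_points(spec.effective_grid):
        if spec.algorithm in ("BAG", "RF"):
            ber = _oob_ber(spec.algorithm, hp, spec.n_trees, X, y, seed)
        else:
            ber = _cv_ber(
                spec.algorithm, hp, spec.n_trees, X, y, train.patients, n_folds, seed
            )
        if ber < best_ber:
            best_hp, best_ber = hp, ber
    if best_hp is None:
        raise ValueError(
            "no grid point produced a defined cross-validated error; "
            "training set is too small or too imbalanced"
        )
    return dict(best_hp, _cv_ber=best_ber)


def fit(
    spec: ModelSpec, hyperparams: dict, train: FeatureDataset, seed: int = 0
) -> TrainedModel:
    """Fit the final model with chosen hyperparameters; deterministic given
    the seed."""
    X = train.X.to_numpy()
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    _check_two_classes(train.y)
    hp = {k: v for k, v in hyperparams.items() if not k.startswith("_")}
    est = _make_estimator(spec.algorithm, hp, spec.n_trees, seed)
    est.fit(X, train.y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        feature_names=train.feature_names,
        hyperparams=hp,
        seed=seed,
    )


def predict(model: TrainedModel, X) -> np.ndarray:
    """+/-1 labels from decision scores; a zero score (tie) maps to +1."""
    if hasattr(X, "to_numpy"):
        X = X.to_numpy()
    X = np.asarray(X)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    scores = model.decision_scores(X)
    return np.where(scores >= 0, SH, NSH)


# ---------------------------------------------------------------------------
# single-feature maximum-likelihood threshold classifier


class NoCrossingError(ValueError):
    """The class-conditional densities have no usable crossing."""


@dataclass(frozen=True)
class ThresholdClassifier:
    """Decision rule on one feature: shockable iff polarity*(x - threshold) >= 0."""

    threshold: float
    polarity: int  # +1: Sh above threshold; -1: Sh below

    def predict(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return np.where(self.polarity * (v - self.threshold) >= 0, SH, NSH)

    def evaluate(self, sh_values, nsh_values) -> MetricSet:
        y = np.concatenate(
            [np.full(len(sh_values), SH), np.full(len(nsh_values), NSH)]
        )
        p = self.predict(np.concatenate([sh_values, nsh_values]))
        return metrics(y, p)


def fit_ml_threshold(
    sh_values, nsh_values, grid_points: int = 2000
) -> ThresholdClassifier:
    """Maximum-likelihood threshold: the point where the kernel-density
    estimates of the two class-conditional densities cross.

    Gaussian KDE with Silverman bandwidth; the crossing is located as the
    argmin of |f(x|Sh) - f(x|NSh)| on a dense grid between the two class
    means (where both densities carry mass).  Polarity puts the class with
    the larger mean above the threshold.
    """
    sh = np.asarray(sh_values, dtype=float)
    nsh = np.asarray(nsh_values, dtype=float)
    if sh.size == 0 or nsh.size == 0:
        raise ValueError("both classes need samples")
    if sh.std() == 0 and nsh.std() == 0:
        raise NoCrossingError("both classes are constant; densities never cross")
    try:
        kde_sh = gaussian_kde(sh, bw_method="silverman")
        kde_nsh = gaussian_kde(nsh, bw_method="silverman")
    except np.linalg.LinAlgError as err:  # constant sample in one class
        raise NoCrossingError(str(err)) from err
    lo, hi = sorted((float(sh.mean()), float(nsh.mean())))
    if hi - lo < 1e-12:
        pooled = np.concatenate([sh, nsh])
        lo, hi = np.percentile(pooled, [0.1, 99.9])
        if hi - lo < 1e-12:
            raise NoCrossingError("class means coincide on a degenerate scale")
    grid = np.linspace(lo, hi, grid_points)
    diff = np.abs(kde_sh(grid) - kde_nsh(grid))
    threshold = float(grid[int(np.argmin(diff))])
    polarity = 1 if sh.mean() >= nsh.mean() else -1
    return ThresholdClassifier(threshold=threshold, polarity=polarity)
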