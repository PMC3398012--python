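"""Cross-validated classifier bake-off and the accuracy/precision metrics.

The reference model is logistic regression with a ridge estimator: the
coefficient vector minimises the negative log-likelihood plus
``lambda * ||beta||^2`` with an unpenalised intercept, solved by damped
Newton iterations to a gradient norm of 1e-8.  Around it sits a
pluggable harness (any object with sklearn fit/predict semantics) with
six built-ins: ridge logistic, 1-NN and k-NN (IB1/IBk analogues),
Gaussian naive Bayes, a decision tree, a random forest and a multilayer
perceptron.

Evaluation is repeated stratified k-fold cross-validation (ten times
ten-fold by default), with per-fold confusion counts and the metrics

    accuracy  = 100 * (TP + TN) / (TP + TN + FP + FN)
    precision = 100 * TP / (TP + FP)        (undefined when TP + FP = 0)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .curation import LabelledDataset

__all__ = [
    "ConfusionCounts",
    "CVResult",
    "ConvergenceError",
    "metrics",
    "RidgeLogistic",
    "ridge_logistic_fit",
    "cross_validate",
    "default_classifiers",
    "classifier_bakeoff",
    "per_descriptor_accuracy",
]


class ConvergenceError(RuntimeError):
    """Newton solver failed to reach the gradient tolerance."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def metrics(c: ConfusionCounts) -> tuple[float, float | None]:
    """(accuracy %, precision %) from a confusion table.

    Precision is ``None`` (not applicable) when no positive predictions
    were made; a zero-total table is an error.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    accuracy = 100.0 * (c.TP + c.TN) / c.total
    precision = 100.0 * c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None
    return accuracy, precision


# ---------------------------------------------------------------------------
# ridge-penalised logistic regression
# ---------------------------------------------------------------------------

class RidgeLogistic(BaseEstimator, ClassifierMixin):
    """Logistic regression with a ridge estimator.

    Minimises ``NLL(beta0, beta) + lam * ||beta||^2`` (intercept not
    penalised) by damped Newton iteration; convergence is declared at
    gradient norm <= ``tol``.

    Parameters
    ----------
    lam : float
        Ridge penalty (default 1e-8, the conventional near-unpenalised
        setting of the reference implementation).
    """

    def __init__(self, lam: float = 1e-8, tol: float = 1e-8,
                 max_iter: int = 200):
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        yarr = np.asarray(y)
        self.classes_ = np.unique(yarr)
        if self.classes_.size != 2:
            raise ValueError("RidgeLogistic needs exactly two classes")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        y01 = (yarr == self.classes_[1]).astype(float)
        n, p = x.shape
        beta = np.zeros(p + 1)  # [intercept, coefficients]
        xa = np.hstack([np.ones((n, 1)), x])
        pen = np.full(p + 1, 2.0 * self.lam)
        pen[0] = 0.0

        def objective(b):
            z = xa @ b
            # log(1 + e^z) - y z, numerically stable
            nll = float(np.sum(np.logaddexp(0.0, z) - y01 * z))
            return nll + self.lam * float(b[1:] @ b[1:])

        obj = objective(beta)
        for it in range(self.max_iter):
            z = xa @ beta
            prob = 1.0 / (1.0 + np.exp(-z))
            grad = xa.T @ (prob - y01) + pen * beta
            gnorm = float(np.linalg.norm(grad))
            if gnorm <= self.tol:
                self.n_iter_ = it
                break
            s = prob * (1.0 - prob)
            hess = (xa * s[:, None]).T @ xa + np.diag(pen)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            # damped: halve until the objective decreases
            alpha = 1.0
            for _ in range(50):
                new_beta = beta - alpha * step
                new_obj = objective(new_beta)
                if new_obj <= obj + 1e-14:
                    break
                alpha *= 0.5
            beta, obj = new_beta, new_obj
        else:
            raise ConvergenceError(
                f"ridge logistic did not converge in {self.max_iter} "
                f"iterations (gradient norm {gnorm:.3e}, lam={self.lam:g})")
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        return self

    def decision_function(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        return self.intercept_ + x @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0.0,
                        self.classes_[1], self.classes_[0])


def ridge_logistic_fit(X, y, lam: float = 1e-8) -> tuple[np.ndarray, float]:
    """Fit ridge logistic regression; returns (coefficients, intercept)."""
    model = RidgeLogistic(lam=lam).fit(X, y)
    return model.coef_, model.intercept_


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    classifier: str
    confusion: list[ConfusionCounts]  # one per (repeat, fold) cell
    mean_accuracy: float
    mean_precision: float | None
    seed: int
    repeats: int
    folds: int
    failures: list[str] = field(default_factory=list)

    def accuracy_per_cell(self) -> np.ndarray:
        return np.array([metrics(c)[0] for c in self.confusion])


def _confusion(y_true: np.ndarray, y_pred: np.ndarray,
               positive) -> ConfusionCounts:
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    return ConfusionCounts(tp, tn, fp, fn)


def cross_validate(classifier, d: LabelledDataset, repeats: int = 10,
                   folds: int = 10, seed: int = 0,
                   standardize: bool = True,
                   name: str | None = None) -> CVResult:
    """Repeated stratified k-fold cross-validation with confusion counts.

    Features are standardised inside each training fold only (no
    leakage).  If the smaller class has fewer members than ``folds`` the
    fold count is reduced with a warning.  A classifier failure on a
    fold is recorded and the fold skipped.
    """
    x = d.X.to_numpy(dtype=float)
    y = d.y
    n = len(y)
    if n < folds:
        raise ValueError(f"n={n} smaller than fold count {folds}")
    min_class = min(d.class_counts())
    if min_class < folds:
        warnings.warn(f"smallest class has {min_class} members; reducing "
                      f"folds from {folds} to {min_class}", UserWarning)
        folds = max(2, min_class)
    label = name or type(classifier).__name__
    confusion: list[ConfusionCounts] = []
    failures: list[str] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=(seed + r) % (2**31))
        for k, (train, test) in enumerate(skf.split(x, y)):
            x_train, x_test = x[train], x[test]
            if standardize:
                scaler = StandardScaler().fit(x_train)
                x_train, x_test = (scaler.transform(x_train),
                                   scaler.transform(x_test))
            model = clone(classifier)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(x_train, y[train])
                    pred = model.predict(x_test)
            except Exception as exc:  # noqa: BLE001 - surfaced in result
                failures.append(f"repeat {r} fold {k}: {exc}")
                continue
            confusion.append(_confusion(y[test], pred, positive=1))
    if not confusion:
        raise RuntimeError(f"{label}: every fold failed ({failures[:3]}...)")
    accs, precs = [], []
    for c in confusion:
        a, p = metrics(c)
        accs.append(a)
        if p is not None:
            precs.append(p)
    return CVResult(
        classifier=label,
        confusion=confusion,
        mean_accuracy=float(np.mean(accs)),
        mean_precision=float(np.mean(precs)) if precs else None,
        seed=seed,
        repeats=repeats,
        folds=folds,
        failures=failures,
    )


def default_classifiers(seed: int = 0, rf_trees: int = 100) -> list[tuple[str, object]]:
    """The six built-in classifiers of the bake-off harness."""
    return [
        ("logistic(ridge)", RidgeLogistic(lam=1e-8)),
        ("IB1(1-NN)", KNeighborsClassifier(n_neighbors=1)),
        ("IBk(3-NN)", KNeighborsClassifier(n_neighbors=3)),
        ("naive_bayes", GaussianNB()),
        ("decision_tree", DecisionTreeClassifier(random_state=seed % (2**31))),
        ("random_forest", RandomForestClassifier(
            n_estimators=rf_trees, random_state=seed % (2**31))),
        ("mlp", MLPClassifier(hidden_layer_sizes=(16,), max_iter=500,
                              random_state=seed % (2**31))),
    ]


def classifier_bakeoff(d: LabelledDataset,
                       classifiers: list[tuple[str, object]] | None = None,
                       seed: int = 0, repeats: int = 10,
                       folds: int = 10) -> list[CVResult]:
    """Cross-validate a menu of classifiers and rank them.

    Results are sorted by mean accuracy descending with ties broken by
    classifier name; the output is always a permutation of the input
    menu (no silent drops).
    """
    if classifiers is None:
        classifiers = default_classifiers(seed)
    if len(classifiers) < 1:
        raise ValueError("empty classifier list")
    results = [
        cross_validate(clf, d, repeats=repeats, folds=folds, seed=seed,
                       name=label)
        for label, clf in classifiers
    ]
    return sorted(results, key=lambda r: (-r.mean_accuracy, r.classifier))


def per_descriptor_accuracy(d: LabelledDataset, classifier=None,
                            seed: int = 0, repeats: int = 10,
                            folds: int = 10) -> dict:
    """Mean CV accuracy of each descriptor alone, plus the combined set.

    Mirrors the individual-versus-combined descriptor profiling: each
    single-column data set is cross-validated separately with the same
    seed, then the full set together.
    """
    if d.X.shape[1] < 1:
        raise ValueError("need at least one descriptor")
    if classifier is None:
        classifier = RidgeLogistic(lam=1e-8)
    individual = {}
    for name in d.X.columns:
        single = LabelledDataset(d.X[[name]].copy(), d.y, d.endpoint)
        res = cross_validate(classifier, single, repeats=repeats,
                             folds=folds, seed=seed, name=str(name))
        individual[str(name)] = res.mean_accuracy
    combined = cross_validate(classifier, d, repeats=repeats, folds=folds,
                              seed=seed, name="combined")
    return {"individual": individual, "combined": combined.mean_accuracy}
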