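"""PLS discriminant analysis with VIP scoring and permutation testing.

Two-class PLS-DA: the binary endpoint is coded as a single centred
{0, 1} response and fitted by the NIPALS PLS1 algorithm with sequential
deflation.  The number of components is chosen by cross-validated Q^2
(7-fold venetian blinds, the SIMCA convention), stopping when an extra
component improves Q^2 by less than a tolerance.

Variable importance in the projection:

    VIP_j = sqrt( p * sum_a w_ja^2 SSY_a / sum_a SSY_a )

with w_a the unit-norm X-weights and SSY_a the Y-variance explained by
component a; the normalisation forces sum_j VIP_j^2 = p.  Descriptors
with VIP >= 1 are the conventional "important" set.

Model significance is assessed by a label-permutation test on R^2Y: the
permuted models are refitted at the component count selected on the
observed data, so the statistic is computed identically under the null.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "PLSDA",
    "autoscale",
    "fit_plsda",
    "vip_scores",
    "select_vip",
    "permutation_test",
]

_EPS = 1e-12


def autoscale(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centre and scale columns to unit sample variance (ddof=1).

    Returns ``(X_scaled, mean, sd)``; raises on constant columns.
    """
    x = np.asarray(X, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd <= _EPS):
        bad = np.flatnonzero(sd <= _EPS)
        raise ValueError(f"constant column(s) at index {bad.tolist()}; "
                         "remove constant descriptors before scaling")
    return (x - mean) / sd, mean, sd


def _nipals_pls1(xs: np.ndarray, yc: np.ndarray, n_components: int):
    """Sequentially deflated PLS1. Returns (W, T, P, c, ssy)."""
    n, p = xs.shape
    x = xs.copy()
    y = yc.copy()
    ws, ts, ps, cs, ssy = [], [], [], [], []
    for _ in range(n_components):
        cov = x.T @ y
        norm = np.linalg.norm(cov)
        if norm <= _EPS:
            break  # residual Y uncorrelated with residual X
        w = cov / norm
        t = x @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        c = float(t @ y) / tt
        p_load = (x.T @ t) / tt
        x = x - np.outer(t, p_load)
        y = y - c * t
        ws.append(w)
        ts.append(t)
        ps.append(p_load)
        cs.append(c)
        ssy.append(c * c * tt)
    if not ws:
        raise ValueError("no PLS component extractable: no X-Y covariance")
    return (np.column_stack(ws), np.column_stack(ts), np.column_stack(ps),
            np.asarray(cs), np.asarray(ssy))


def _regression_coef(w: np.ndarray, p: np.ndarray, c: np.ndarray) -> np.ndarray:
    """b = W (P'W)^-1 c, the X-space regression vector."""
    return w @ np.linalg.solve(p.T @ w, c)


class PLSDA(BaseEstimator, ClassifierMixin):
    """Two-class PLS-DA estimator (NIPALS PLS1 on a centred 0/1 response).

    Parameters
    ----------
    n_components : int or "auto"
        Fixed component count, or "auto" for Q^2-based selection.
    max_components : int
        Upper bound on components when selecting automatically.
    q2_tol : float
        Minimum Q^2 improvement required to accept another component.
    cv_folds : int
        Venetian-blind fold count for Q^2.
    scale : bool
        Autoscale X inside ``fit`` (unit sample variance).

    Attributes (after fit)
    ----------------------
    n_components_, x_weights_, x_scores_, x_loadings_, y_loadings_,
    ssy_, r2y_, q2_, vip_, coef_, feature_names_in_
    """

    def __init__(self, n_components="auto", max_components: int = 10,
                 q2_tol: float = 0.01, cv_folds: int = 7, scale: bool = True):
        self.n_components = n_components
        self.max_components = max_components
        self.q2_tol = q2_tol
        self.cv_folds = cv_folds
        self.scale = scale

    # -- helpers ------------------------------------------------------------

    def _encode_y(self, y) -> np.ndarray:
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("PLSDA is strictly two-class")
        return (y == self.classes_[1]).astype(float)

    def _q2(self, xs: np.ndarray, y01: np.ndarray, n_components: int) -> np.ndarray:
        """Cumulative Q^2 for 1..n_components via venetian blinds."""
        n = xs.shape[0]
        folds = min(self.cv_folds, n)
        press = np.zeros(n_components)
        for f in range(folds):
            test = np.arange(n) % folds == f
            train = ~test
            y_train = y01[train]
            y_mean = y_train.mean()
            yc = y_train - y_mean
            if np.abs(yc).sum() <= _EPS:
                continue  # degenerate blind: single class in training split
            try:
                w, _, p, c, _ = _nipals_pls1(xs[train], yc, n_components)
            except ValueError:
                continue
            for a in range(n_components):
                # folds that extracted fewer components reuse their deepest model
                upto = min(a, w.shape[1] - 1) + 1
                b = _regression_coef(w[:, :upto], p[:, :upto], c[:upto])
                pred = y_mean + xs[test] @ b
                press[a] += float(((y01[test] - pred) ** 2).sum())
        ss_tot = float(((y01 - y01.mean()) ** 2).sum())
        return 1.0 - press / ss_tot

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        x = np.asarray(X, dtype=float)
        if x.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = x.shape
        if n < 10:
            raise ValueError("PLS-DA needs at least 10 samples")
        y01 = self._encode_y(y)
        n_pos = int(y01.sum())
        if n_pos == 0 or n_pos == n:
            raise ValueError("no Y-variance: single-class input")
        if abs(n_pos - (n - n_pos)) > max(2, 0.2 * n):
            warnings.warn("class sizes are unbalanced; balanced 1:1 input "
                          "is recommended for PLS-DA selection", UserWarning)
        if self.scale:
            xs, self.x_mean_, self.x_std_ = autoscale(x)
        else:
            xs = x - x.mean(axis=0)
            self.x_mean_, self.x_std_ = x.mean(axis=0), np.ones(p)
        self.y_mean_ = y01.mean()
        yc = y01 - self.y_mean_

        a_max = min(self.max_components, p, n - 1)
        if self.n_components == "auto":
            q2 = self._q2(xs, y01, a_max)
            a = 1
            while a < len(q2) and (q2[a] - q2[a - 1]) >= self.q2_tol:
                a += 1
            self.q2_path_ = q2
            self.q2_ = float(q2[a - 1]) if len(q2) else float("nan")
        else:
            a = int(self.n_components)
            if a < 1:
                raise ValueError("n_components must be >= 1")
            a = min(a, a_max)
            q2 = self._q2(xs, y01, a)
            self.q2_path_ = q2
            self.q2_ = float(q2[-1]) if len(q2) else float("nan")

        w, t, p_load, c, ssy = _nipals_pls1(xs, yc, a)
        self.n_components_ = w.shape[1]
        self.x_weights_ = w
        self.x_scores_ = t
        self.x_loadings_ = p_load
        self.y_loadings_ = c
        self.ssy_ = ssy
        ss_tot = float(yc @ yc)
        self.r2y_ = float(ssy.sum() / ss_tot)
        self.coef_ = _regression_coef(w, p_load, c)
        self.vip_ = self._vip()
        return self

    def _vip(self) -> np.ndarray:
        ssy = self.ssy_
        total = ssy.sum()
        if total <= _EPS:
            raise ValueError("zero explained Y-variance; VIP undefined")
        p = self.x_weights_.shape[0]
        contrib = (self.x_weights_ ** 2) @ ssy
        return np.sqrt(p * contrib / total)

    def decision_function(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        xs = (x - self.x_mean_) / self.x_std_
        return self.y_mean_ + xs @ self.coef_

    def predict(self, X) -> np.ndarray:
        yhat = self.decision_function(X)
        return np.where(yhat >= 0.5, self.classes_[1], self.classes_[0])

    def transform(self, X) -> np.ndarray:
        """Project onto the extracted score directions."""
        x = np.asarray(X, dtype=float)
        xs = (x - self.x_mean_) / self.x_std_
        r = self.x_weights_ @ np.linalg.inv(
            self.x_loadings_.T @ self.x_weights_)
        return xs @ r

    # -- reporting ----------------------------------------------------------

    def vip_table(self) -> pd.Series:
        names = getattr(self, "feature_names_in_",
                        np.arange(len(self.vip_)).astype(str))
        return pd.Series(self.vip_, index=names, name="VIP")


def fit_plsda(X, y, A_max: int = 10, **kwargs) -> PLSDA:
    """Fit PLS-DA with automatic component selection up to ``A_max``."""
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    return PLSDA(n_components="auto", max_components=A_max, **kwargs).fit(X, y)


def vip_scores(model: PLSDA) -> pd.Series:
    """VIP per descriptor for a fitted model (sum of squares = p)."""
    if not hasattr(model, "vip_"):
        raise ValueError("model is not fitted")
    return model.vip_table()


def select_vip(model: PLSDA, cutoff: float = 1.0) -> list[str]:
    """Descriptor names with VIP >= cutoff, sorted by VIP descending.

    Ties are broken by name so the selection is deterministic and
    invariant to column order.
    """
    vip = vip_scores(model)
    chosen = vip[vip >= cutoff]
    return [str(name) for name, _ in
            sorted(chosen.items(), key=lambda kv: (-kv[1], str(kv[0])))]


def permutation_test(X, y, n_perm: int = 999, seed: int = 0,
                     statistic: str = "r2y", A_max: int = 10) -> dict:
    """Label-permutation significance of the PLS-DA separation.

    The observed model selects its component count by Q^2; each permuted
    model is refitted at that same fixed count and the statistic
    (default R^2Y) recomputed.  p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if statistic not in ("r2y", "q2"):
        raise ValueError("statistic must be 'r2y' or 'q2'")
    observed = fit_plsda(X, y, A_max=A_max)
    a = observed.n_components_
    obs_stat = observed.r2y_ if statistic == "r2y" else observed.q2_
    xs = (np.asarray(X, dtype=float) - observed.x_mean_) / observed.x_std_
    y01 = (np.asarray(y) == observed.classes_[1]).astype(float)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = rng.permutation(y01)
        yc = yp - yp.mean()
        if statistic == "r2y":
            try:
                _, _, _, _, ssy = _nipals_pls1(xs, yc, a)
            except ValueError:
                stat = 0.0
            else:
                stat = float(ssy.sum() / (yc @ yc))
        else:
            perm_model = PLSDA(n_components=a).fit(X, yp)
            stat = perm_model.q2_
        if stat >= obs_stat:
            count += 1
    p_value = (1 + count) / (1 + n_perm)
    return {"p_value": p_value, "observed": obs_stat, "statistic": statistic,
            "n_components": a, "n_perm": n_perm}
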