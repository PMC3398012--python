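"""Correlation-based feature selection (CFS) with best-first search.

A candidate subset S of k features is scored by Hall's merit heuristic

    merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where ``r_cf`` is the mean absolute feature-class correlation over S and
``r_ff`` the mean absolute feature-feature correlation over pairs in S.
High merit rewards relevance (correlation with the class) and punishes
redundancy (correlation within the subset).  Correlations are Pearson,
computed on standardised features against the +1/-1 class vector.

The search is best-first from the empty set over add-one expansions,
terminating after a fixed number of consecutive non-improving
expansions; ties are broken by feature name so the result is
deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

__all__ = ["FeatureSubset", "merit", "best_first_search", "CFSSelector"]


@dataclass(frozen=True)
class FeatureSubset:
    names: tuple[str, ...]
    merit: float


def _correlations(X: pd.DataFrame, y: np.ndarray):
    """(|feature-class| vector, |feature-feature| matrix) of Pearson r."""
    x = X.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd <= 1e-12):
        bad = [str(X.columns[i]) for i in np.flatnonzero(sd <= 1e-12)]
        raise ValueError(f"zero-variance feature(s): {bad}")
    xs = (x - x.mean(axis=0)) / sd
    yv = np.asarray(y, dtype=float)
    ys = (yv - yv.mean()) / yv.std(ddof=1)
    n = x.shape[0]
    r_cf = np.abs(xs.T @ ys) / (n - 1)
    r_ff = np.abs(xs.T @ xs) / (n - 1)
    np.fill_diagonal(r_ff, 1.0)
    return r_cf, r_ff


def _merit_from_corr(idx: tuple[int, ...], r_cf: np.ndarray,
                     r_ff: np.ndarray) -> float:
    k = len(idx)
    if k == 0:
        return 0.0
    sel = list(idx)
    mean_cf = float(r_cf[sel].mean())
    if k == 1:
        return mean_cf
    sub = r_ff[np.ix_(sel, sel)]
    iu = np.triu_indices(k, k=1)
    mean_ff = float(sub[iu].mean())
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def merit(subset, X: pd.DataFrame, y) -> float:
    """Hall's CFS merit of a named feature subset (k=1 gives |r_cf|)."""
    names = list(subset)
    if not names:
        raise ValueError("subset must be non-empty")
    missing = [n for n in names if n not in X.columns]
    if missing:
        raise KeyError(f"unknown feature(s): {missing}")
    r_cf, r_ff = _correlations(X[names], np.asarray(y))
    return _merit_from_corr(tuple(range(len(names))), r_cf, r_ff)


def best_first_search(X: pd.DataFrame, y, stall_limit: int = 5,
                      max_subsets: int | None = None) -> FeatureSubset:
    """Best-first forward search over CFS merit.

    Expands the highest-merit open subset by one feature at a time and
    stops after ``stall_limit`` consecutive expansions that fail to beat
    the best merit seen.  With few enough features this recovers the
    exhaustive optimum.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    names = [str(c) for c in X.columns]
    order = np.argsort(names)  # deterministic tie-break by name
    r_cf, r_ff = _correlations(X, np.asarray(y))

    def sorted_names(idx: tuple[int, ...]) -> tuple[str, ...]:
        return tuple(sorted(names[i] for i in idx))

    best_idx: tuple[int, ...] = ()
    best_merit = 0.0
    # heap entries: (-merit, tie-break names, index tuple)
    open_heap: list[tuple[float, tuple[str, ...], tuple[int, ...]]] = [
        (0.0, (), ())]
    visited: set[frozenset[int]] = {frozenset()}
    stall = 0
    expansions = 0
    while open_heap and stall < stall_limit:
        _, _, current = heapq.heappop(open_heap)
        expansions += 1
        if max_subsets is not None and expansions > max_subsets:
            break
        improved = False
        in_set = set(current)
        for i in order:
            if i in in_set:
                continue
            cand = tuple(sorted(current + (int(i),)))
            key = frozenset(cand)
            if key in visited:
                continue
            visited.add(key)
            m = _merit_from_corr(cand, r_cf, r_ff)
            heapq.heappush(open_heap, (-m, sorted_names(cand), cand))
            if m > best_merit + 1e-12:
                best_merit, best_idx = m, cand
                improved = True
        stall = 0 if improved else stall + 1
    return FeatureSubset(names=sorted_names(best_idx), merit=best_merit)


class CFSSelector(BaseEstimator, SelectorMixin):
    """sklearn-style transformer wrapping CFS best-first search.

    Attributes (after fit): ``support_``, ``subset_`` (FeatureSubset),
    ``merit_``.
    """

    def __init__(self, stall_limit: int = 5):
        self.stall_limit = stall_limit

    def fit(self, X, y):
        frame = (X if isinstance(X, pd.DataFrame)
                 else pd.DataFrame(np.asarray(X, dtype=float)))
        frame.columns = [str(c) for c in frame.columns]
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        self.subset_ = best_first_search(frame, y, self.stall_limit)
        self.merit_ = self.subset_.merit
        chosen = set(self.subset_.names)
        self.support_ = np.array([c in chosen for c in frame.columns])
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_
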