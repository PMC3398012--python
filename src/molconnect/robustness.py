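"""Small-data-set robustness scoring by resampling.

To check that a model's accuracy is not an artefact of data-set size,
the molecules are resampled with replacement into many small data sets
(1000 sets of 100 molecules by convention), each is cross-validated
(10-fold) with the reference classifier, and m counts how many small
sets reach at least the full-data reference accuracy.  The score is

    score = 10 * m / n            significant when score >= 5

i.e. the fraction of qualifying small sets scaled to 0-10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .curation import LabelledDataset
from .mlbench import RidgeLogistic, cross_validate

logger = logging.getLogger(__name__)

__all__ = ["RobustnessScore", "score_from_counts", "small_set_score",
           "SIGNIFICANCE_THRESHOLD"]

SIGNIFICANCE_THRESHOLD = 5.0


@dataclass(frozen=True)
class RobustnessScore:
    m: int
    n: int
    score: float
    significant: bool
    reference_accuracy: float | None = None
    accuracies: tuple[float, ...] | None = None  # per-small-set CV accuracy
    redraws: int = 0

    def __str__(self) -> str:
        flag = "significant" if self.significant else "not significant"
        return f"score {self.score:.2f} (m={self.m}/{self.n}; {flag})"


def score_from_counts(m: int, n: int,
                      reference_accuracy: float | None = None) -> RobustnessScore:
    """Pure arithmetic: score = 10*m/n with the >=5 significance flag.

    Exact rational arithmetic, reported to full float precision (display
    to two decimals).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= m <= n:
        raise ValueError(f"m={m} must lie in [0, n={n}]")
    score = 10.0 * m / n
    return RobustnessScore(m=int(m), n=int(n), score=score,
                           significant=score >= SIGNIFICANCE_THRESHOLD,
                           reference_accuracy=reference_accuracy)


def small_set_score(d: LabelledDataset, classifier=None,
                    reference_accuracy: float = None, n_sets: int = 1000,
                    set_size: int = 100, seed: int = 0, folds: int = 10,
                    max_redraws: int = 1000) -> RobustnessScore:
    """Resampling robustness score of a labelled data set.

    Each of ``n_sets`` seeded resamples (``set_size`` molecules, drawn
    uniformly with replacement, unstratified) is cross-validated and
    counted as qualifying when its CV accuracy reaches
    ``reference_accuracy``.  Single-class resamples are redrawn and
    logged.
    """
    if reference_accuracy is None or not (0.0 < reference_accuracy <= 100.0):
        raise ValueError("reference_accuracy must lie in (0, 100]")
    if classifier is None:
        classifier = RidgeLogistic(lam=1e-8)
    if set_size > d.n:
        logger.warning("set_size %d exceeds data size %d", set_size, d.n)
    rng = np.random.default_rng(seed)
    accuracies = []
    redraws = 0
    for s in range(n_sets):
        for _ in range(max_redraws):
            idx = rng.integers(0, d.n, size=set_size)
            y_sub = d.y[idx]
            if np.unique(y_sub).size == 2:
                break
            redraws += 1
            logger.info("resample %d single-class; redrawing", s)
        else:
            raise RuntimeError("could not draw a two-class resample")
        subset = LabelledDataset(d.X.iloc[idx].reset_index(drop=True),
                                 y_sub, d.endpoint)
        res = cross_validate(classifier, subset, repeats=1, folds=folds,
                             seed=int(rng.integers(2**31)))
        accuracies.append(res.mean_accuracy)
    acc = np.asarray(accuracies)
    m = int((acc >= reference_accuracy).sum())
    base = score_from_counts(m, n_sets, reference_accuracy)
    return RobustnessScore(m=base.m, n=base.n, score=base.score,
                           significant=base.significant,
                           reference_accuracy=reference_accuracy,
                           accuracies=tuple(accuracies), redraws=redraws)
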