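"""Forced-choice scoring: selections, quiz accuracy, Mann-Whitney AUC, ROC.

The central identity: a score-based selector applied to every
(positive, negative) pair of a cohort answers the forced-choice quiz
correctly with relative frequency exactly equal to the Mann-Whitney
AUC of the scores, ties credited one half on both sides.  Quiz accuracy
on a random one-to-one pairing is therefore an unbiased estimate of the
ROC AUC, which is why the quiz score of a selector can be read as an
AUC.  All score-based outputs are invariant under strictly increasing
transformations of the score scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .types import (
    CHOSE_NEGATIVE,
    CHOSE_POSITIVE,
    TIE,
    PairRecord,
    RaterPerformance,
    SelectionVector,
    ValidationError,
)

__all__ = [
    "model_selections",
    "quiz_accuracy",
    "mann_whitney_auc",
    "roc_curve",
    "RocResult",
]

MODEL_SELECTOR_ID = "model"


def model_selections(
    pairs: Sequence[PairRecord],
    scores: Mapping[str, float],
    selector_id: str = MODEL_SELECTOR_ID,
) -> SelectionVector:
    """Per pair, pick the embryo with the strictly higher score.

    Exactly equal scores yield a tie, credited one half downstream so
    that the accuracy/AUC identity holds.  A missing score raises,
    naming the embryo.
    """
    values = np.empty(len(pairs))
    for i, p in enumerate(pairs):
        for eid in p.embryo_ids:
            if eid not in scores or scores[eid] is None:
                raise ValidationError(f"no score for embryo {eid!r}")
        sp, sn = scores[p.positive_embryo_id], scores[p.negative_embryo_id]
        values[i] = (
            CHOSE_POSITIVE if sp > sn else CHOSE_NEGATIVE if sp < sn else TIE
        )
    return SelectionVector(
        selector_id=selector_id,
        pair_ids=[p.pair_id for p in pairs],
        values=values,
        allow_ties=True,
    )


def quiz_accuracy(selection: SelectionVector) -> RaterPerformance:
    """Fraction of pairs answered correctly, ties credited 0.5."""
    if selection.n_pairs == 0:
        raise ValidationError("empty selection: quiz accuracy undefined")
    n_correct = float(np.sum(selection.values))
    return RaterPerformance(
        selector_id=selection.selector_id,
        n_pairs=selection.n_pairs,
        n_correct=n_correct,
        accuracy=n_correct / selection.n_pairs,
    )


def mann_whitney_auc(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> float:
    """P(positive score > negative score) + 0.5 P(equal), over all pairs.

    Computed via midranks in O(n log n); exactly equal to the
    brute-force pair count (#{p>n} + 0.5 #{p=n}) / (|pos| |neg|).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class RocResult:
    """ROC curve swept over the distinct score values, descending."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_positive: int
    n_negative: int

    @property
    def curve(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def roc_curve(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> RocResult:
    """ROC over pooled positive and negative scores.

    The curve starts at (0, 0), ends at (1, 1), and its trapezoidal
    area equals :func:`mann_whitney_auc` (ties produce the diagonal
    segments the trapezoid rule credits at one half).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score lists must be nonempty")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # one operating point after each distinct score value
    distinct = np.r_[np.nonzero(np.diff(scores))[0], scores.size - 1]
    tp = np.cumsum(labels)[distinct]
    fp = np.cumsum(1 - labels)[distinct]
    tpr = np.r_[0.0, tp / pos.size]
    fpr = np.r_[0.0, fp / neg.size]
    thresholds = np.r_[np.inf, scores[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        auc=auc,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
    )
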