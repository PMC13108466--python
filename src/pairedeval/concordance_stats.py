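"""Paired comparison statistics for forced-choice selectors.

Implements the McNemar test on discordant pairs (exact conditional
binomial plus both chi-square variants), majority-vote committee
aggregation with tie credit, Fleiss kappa for multi-rater agreement,
pairwise agreement summaries, and the experience-accuracy correlation.

The McNemar test compares two selectors on the same quiz using only the
discordant items: b pairs where the reference selector is correct and
the comparator wrong, c pairs the other way round.  Under the null of
equal marginal accuracy, b | (b + c) ~ Binomial(b + c, 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .types import (
    ChoiceMatrix,
    RaterPerformance,
    RaterRecord,
    SelectionVector,
    ValidationError,
)

__all__ = [
    "McNemarResult",
    "CommitteeResult",
    "KappaResult",
    "CorrelationResult",
    "AgreementSummary",
    "discordant_counts",
    "mcnemar_test",
    "mcnemar_exact_pvalues",
    "committee_votes",
    "committee_vs_model_mcnemar",
    "RandomizedMcNemarResult",
    "FractionalMcNemarResult",
    "per_rater_mcnemar",
    "mean_rater_vs_model_mcnemar",
    "fleiss_kappa",
    "agreement_summary",
    "experience_correlation",
    "holm_adjust",
]


# --------------------------------------------------------------------------
# McNemar


@dataclass(frozen=True)
class McNemarResult:
    """Discordant counts and the test under three variants.

    ``p_exact`` is the two-sided conditional binomial p-value
    ``min(1, 2 P(Bin(b+c, 1/2) <= min(b, c)))``; ``p_chi2`` uses the
    statistic (b-c)^2/(b+c) on 1 df and ``p_chi2_cc`` the
    continuity-corrected (|b-c|-1)^2/(b+c).
    """

    b: int
    c: int
    statistic_chi2: float
    p_chi2: float
    p_chi2_cc: float
    p_exact: float
    method_reported: str = "exact"
    degenerate: bool = False

    @property
    def n_discordant(self) -> int:
        return self.b + self.c

    @property
    def p_value(self) -> float:
        return {
            "exact": self.p_exact,
            "chi2": self.p_chi2,
            "chi2_cc": self.p_chi2_cc,
        }[self.method_reported]


def discordant_counts(
    reference: SelectionVector, comparator: SelectionVector
) -> tuple[int, int]:
    """Count (b, c): reference-correct-only and comparator-correct-only.

    Both selectors must cover the same pairs and contain no ties
    (tie handling is the caller's responsibility).  Concordant pairs
    are excluded from both counts.
    """
    if reference.pair_ids != comparator.pair_ids:
        raise ValidationError("selectors cover different pair sets")
    if reference.has_ties() or comparator.has_ties():
        raise ValidationError(
            "discordant_counts requires tie-free selections; "
            "apply a tie policy first"
        )
    r, m = reference.values, comparator.values
    b = int(np.sum((r == 1) & (m == 0)))
    c = int(np.sum((r == 0) & (m == 1)))
    return b, c


def mcnemar_test(b: int, c: int, method: str = "exact") -> McNemarResult:
    """McNemar test from the two discordant counts alone."""
    if b < 0 or c < 0:
        raise ValidationError("discordant counts must be nonnegative")
    if method not in ("exact", "chi2", "chi2_cc"):
        raise ValidationError(f"unknown method {method!r}")
    n = b + c
    if n == 0:
        return McNemarResult(
            b=0, c=0, statistic_chi2=0.0, p_chi2=1.0, p_chi2_cc=1.0,
            p_exact=1.0, method_reported=method, degenerate=True,
        )
    stat = (b - c) ** 2 / n
    stat_cc = (abs(b - c) - 1) ** 2 / n
    return McNemarResult(
        b=b,
        c=c,
        statistic_chi2=float(stat),
        p_chi2=float(stats.chi2.sf(stat, df=1)),
        p_chi2_cc=float(stats.chi2.sf(stat_cc, df=1)),
        p_exact=float(mcnemar_exact_pvalues(b, c)),
        method_reported=method,
    )


def mcnemar_exact_pvalues(b, c):
    """Vectorized two-sided exact conditional binomial p-value.

    ``min(1, 2 P(Bin(b+c, 1/2) <= min(b, c)))``; 1.0 where b = c = 0.
    """
    b = np.asarray(b)
    c = np.asarray(c)
    n = b + c
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.binom.cdf(np.minimum(b, c), np.maximum(n, 1), 0.5)
    p = np.where(n == 0, 1.0, np.minimum(p, 1.0))
    return p if p.shape else float(p)


# --------------------------------------------------------------------------
# Committee


@dataclass
class CommitteeResult:
    """Majority vote over raters, per pair; equal counts recorded as ties.

    Accuracy credits each tie one half ("the committee is correct 50%
    of the time on ties").  Pairs no rater answered are excluded and
    listed in ``excluded_pair_ids``.
    """

    selection: SelectionVector  # selector_id "committee", ties allowed
    votes_positive: np.ndarray  # raters choosing the positive embryo, per pair
    votes_total: np.ndarray
    excluded_pair_ids: list[str] = field(default_factory=list)

    @property
    def n_tie(self) -> int:
        return self.selection.n_ties

    @property
    def performance(self) -> RaterPerformance:
        from .selection_scoring import quiz_accuracy

        return quiz_accuracy(self.selection)

    @property
    def accuracy(self) -> float:
        return self.performance.accuracy


def committee_votes(choices: ChoiceMatrix) -> CommitteeResult:
    """Aggregate the rater choice matrix into the committee selector."""
    if choices.n_raters < 1:
        raise ValidationError("committee requires at least one rater")
    answered = choices.choices != ChoiceMatrix.MISSING
    pos_votes = np.sum((choices.choices == 1) & answered, axis=0)
    total = answered.sum(axis=0)
    neg_votes = total - pos_votes
    keep = total > 0
    values = np.where(pos_votes > neg_votes, 1.0,
                      np.where(pos_votes < neg_votes, 0.0, 0.5))[keep]
    sel = SelectionVector(
        selector_id="committee",
        pair_ids=[pid for pid, k in zip(choices.pair_ids, keep) if k],
        values=values,
        allow_ties=True,
    )
    return CommitteeResult(
        selection=sel,
        votes_positive=pos_votes[keep],
        votes_total=total[keep],
        excluded_pair_ids=[pid for pid, k in zip(choices.pair_ids, keep) if not k],
    )


@dataclass(frozen=True)
class RandomizedMcNemarResult:
    """McNemar between tie-carrying selectors under random tie-breaking.

    Each tie is broken by an independent fair coin; the test is
    recomputed over seeded replicates and the median p-value with an
    interquartile band is reported.  With no ties every replicate is
    identical and the result coincides with :func:`mcnemar_test`.
    """

    tie_policy: str
    n_resamples: int
    n_ties_broken: int
    b_mean: float
    c_mean: float
    p_exact_median: float
    p_exact_q25: float
    p_exact_q75: float
    p_chi2_median: float
    p_chi2_cc_median: float


@dataclass(frozen=True)
class FractionalMcNemarResult:
    """Chi-square McNemar on fractionally allocated tie mass.

    A half-correct selection contributes weight 0.5 to each correctness
    cell, so b and c may be non-integers; the exact conditional test is
    unavailable under this policy and is flagged as such.
    """

    tie_policy: str
    b: float
    c: float
    statistic_chi2: float
    p_chi2: float
    p_chi2_cc: float
    exact_available: bool = False


def _fractional_counts(r: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    # product allocation: a tie (0.5) splits its mass over correct/incorrect
    b = float(np.sum(r * (1.0 - m)))
    c = float(np.sum((1.0 - r) * m))
    return b, c


def committee_vs_model_mcnemar(
    committee: CommitteeResult,
    model: SelectionVector,
    tie_policy: str = "randomized",
    n_resamples: int = 999,
    seed: int = 0,
):
    """Compare the committee with the score-based selector by McNemar.

    ``tie_policy="randomized"`` (default) breaks every committee (and
    model) tie with an independent fair coin, repeats the exact test
    over ``n_resamples`` seeded replicates, and reports median p-values
    with an interquartile band.  ``tie_policy="fractional"`` allocates
    each tie half to each correctness cell and computes the chi-square
    variants on the fractional counts.
    """
    if committee.selection.pair_ids != model.pair_ids:
        raise ValidationError("committee and model cover different pair sets")
    r = committee.selection.values
    m = model.values
    if tie_policy == "fractional":
        b, c = _fractional_counts(r, m)
        n = b + c
        stat = (b - c) ** 2 / n if n > 0 else 0.0
        stat_cc = (abs(b - c) - 1) ** 2 / n if n > 0 else 0.0
        return FractionalMcNemarResult(
            tie_policy="fractional",
            b=b,
            c=c,
            statistic_chi2=float(stat),
            p_chi2=float(stats.chi2.sf(stat, df=1)) if n > 0 else 1.0,
            p_chi2_cc=float(stats.chi2.sf(stat_cc, df=1)) if n > 0 else 1.0,
        )
    if tie_policy != "randomized":
        raise ValidationError(f"unknown tie_policy {tie_policy!r}")
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")

    rng = np.random.default_rng(seed)
    r_ties = r == 0.5
    m_ties = m == 0.5
    n_ties = int(r_ties.sum() + m_ties.sum())
    bs = np.empty(n_resamples)
    cs = np.empty(n_resamples)
    for k in range(n_resamples):
        rk = np.where(r_ties, rng.integers(0, 2, size=r.size).astype(float), r)
        mk = np.where(m_ties, rng.integers(0, 2, size=m.size).astype(float), m)
        bs[k] = np.sum((rk == 1) & (mk == 0))
        cs[k] = np.sum((rk == 0) & (mk == 1))
    p_exact = mcnemar_exact_pvalues(bs, cs)
    n = bs + cs
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(n > 0, (bs - cs) ** 2 / np.maximum(n, 1), 0.0)
        stat_cc = np.where(
            n > 0, (np.abs(bs - cs) - 1) ** 2 / np.maximum(n, 1), 0.0
        )
    p_chi2 = np.where(n > 0, stats.chi2.sf(stat, df=1), 1.0)
    p_chi2_cc = np.where(n > 0, stats.chi2.sf(stat_cc, df=1), 1.0)
    return RandomizedMcNemarResult(
        tie_policy="randomized",
        n_resamples=n_resamples,
        n_ties_broken=n_ties,
        b_mean=float(bs.mean()),
        c_mean=float(cs.mean()),
        p_exact_median=float(np.median(p_exact)),
        p_exact_q25=float(np.quantile(p_exact, 0.25)),
        p_exact_q75=float(np.quantile(p_exact, 0.75)),
        p_chi2_median=float(np.median(p_chi2)),
        p_chi2_cc_median=float(np.median(p_chi2_cc)),
    )


def per_rater_mcnemar(
    choices: ChoiceMatrix, model: SelectionVector
) -> list[dict]:
    """Per-rater McNemar vs the model, on the pairs each rater answered.

    Model ties on a rater's pairs are allocated fractionally (0.5 to
    each correctness cell) for the chi-square variants; the exact
    variant then uses counts rounded to the nearest integer and is
    flagged.  Rows keep rater order.
    """
    model_by_pair = dict(zip(model.pair_ids, model.values))
    rows = []
    for rid in choices.rater_ids:
        sel = choices.rater_selection(rid)
        m = np.array([model_by_pair[pid] for pid in sel.pair_ids])
        r = sel.values
        b_f, c_f = _fractional_counts(r, m)
        fractional = bool(np.any(m == 0.5))
        b, c = int(round(b_f)), int(round(c_f))
        res = mcnemar_test(b, c)
        n_correct = float(r.sum())
        rows.append(
            {
                "rater_id": rid,
                "n_pairs": sel.n_pairs,
                "accuracy": n_correct / sel.n_pairs,
                "b": b_f,
                "c": c_f,
                "p_exact": res.p_exact,
                "p_chi2": res.p_chi2,
                "p_chi2_cc": res.p_chi2_cc,
                "exact_counts_rounded": fractional,
            }
        )
    return rows


@dataclass(frozen=True)
class MeanRaterMcNemarResult:
    """McNemar applied to discordant counts averaged across raters.

    b and c are the mean per-rater discordant counts vs the model; the
    chi-square variants use the raw means, the exact variant the means
    rounded to the nearest integer (flagged via ``b_rounded`` /
    ``c_rounded``).
    """

    b_mean: float
    c_mean: float
    b_rounded: int
    c_rounded: int
    statistic_chi2: float
    p_chi2: float
    p_chi2_cc: float
    p_exact: float


def mean_rater_vs_model_mcnemar(
    choices: ChoiceMatrix, model: SelectionVector
) -> MeanRaterMcNemarResult:
    """Average per-rater discordant counts, then test the means."""
    rows = per_rater_mcnemar(choices, model)
    if not rows:
        raise ValidationError("no raters")
    b_mean = float(np.mean([r["b"] for r in rows]))
    c_mean = float(np.mean([r["c"] for r in rows]))
    n = b_mean + c_mean
    stat = (b_mean - c_mean) ** 2 / n if n > 0 else 0.0
    stat_cc = (abs(b_mean - c_mean) - 1) ** 2 / n if n > 0 else 0.0
    b_r, c_r = int(round(b_mean)), int(round(c_mean))
    return MeanRaterMcNemarResult(
        b_mean=b_mean,
        c_mean=c_mean,
        b_rounded=b_r,
        c_rounded=c_r,
        statistic_chi2=float(stat),
        p_chi2=float(stats.chi2.sf(stat, df=1)) if n > 0 else 1.0,
        p_chi2_cc=float(stats.chi2.sf(stat_cc, df=1)) if n > 0 else 1.0,
        p_exact=float(mcnemar_exact_pvalues(b_r, c_r)),
    )


# --------------------------------------------------------------------------
# Fleiss kappa


@dataclass(frozen=True)
class KappaResult:
    """Fleiss's chance-corrected multi-rater agreement over 2 categories."""

    kappa: float
    n_items: int
    n_raters: int
    category_scheme: str
    p_bar: float
    p_e_bar: float
    undefined: bool = False


def fleiss_kappa(
    choices: ChoiceMatrix, category_scheme: str = "choice-identity"
) -> KappaResult:
    """Fleiss kappa of the rater choices, (P - Pe) / (1 - Pe).

    Items answered by fewer than two raters are excluded (their count
    is reflected in ``n_items``).  In this forced-choice design the
    successful embryo is always the correct answer, so the
    ``choice-identity`` and ``correctness`` category codings induce the
    same binary partition and the same kappa; both labels are accepted.
    """
    if category_scheme not in ("choice-identity", "correctness"):
        raise ValidationError(f"unknown category_scheme {category_scheme!r}")
    if choices.n_raters < 2:
        raise ValidationError("Fleiss kappa requires at least two raters")
    answered = choices.choices != ChoiceMatrix.MISSING
    n_i = answered.sum(axis=0)
    keep = n_i >= 2
    if not keep.any():
        raise ValidationError("no item was answered by two or more raters")
    n_pos = np.sum((choices.choices == 1) & answered, axis=0)[keep]
    n_i = n_i[keep]
    n_neg = n_i - n_pos
    p_i = (n_pos**2 + n_neg**2 - n_i) / (n_i * (n_i - 1.0))
    p_bar = float(p_i.mean())
    total = float(n_i.sum())
    p_j = np.array([n_pos.sum() / total, n_neg.sum() / total])
    p_e = float(np.sum(p_j**2))
    if p_e >= 1.0:
        # every response in one category: perfect agreement iff P = 1
        kappa, undefined = (1.0, False) if p_bar == 1.0 else (float("nan"), True)
    else:
        kappa, undefined = (p_bar - p_e) / (1.0 - p_e), False
    return KappaResult(
        kappa=float(kappa),
        n_items=int(keep.sum()),
        n_raters=choices.n_raters,
        category_scheme=category_scheme,
        p_bar=p_bar,
        p_e_bar=p_e,
        undefined=undefined,
    )


# --------------------------------------------------------------------------
# Agreement


@dataclass
class AgreementSummary:
    """Pairwise agreement between all selectors (raters, model, committee).

    Agreement between two selectors is the fraction of commonly
    answered pairs on which they chose the same embryo; a tie counts
    as agreeing with either definite choice one half of the time
    (the expectation under a fair-coin tie break).  ``agree_or_better``
    is the fraction of pairs on which the model either matches the
    committee or out-performs it (committee ties credited 0.5
    agreement plus 0.5 times model correctness).
    """

    selector_ids: list[str]
    matrix: np.ndarray
    mean_rater_rater: float
    mean_model_rater: float
    model_committee: float
    agree_or_better: float


def _pairwise_agreement(v1: np.ndarray, v2: np.ndarray) -> float:
    # expectation of "same embryo chosen" under fair-coin tie breaks
    return float(np.mean(v1 * v2 + (1.0 - v1) * (1.0 - v2)))


def agreement_summary(
    choices: ChoiceMatrix,
    model: SelectionVector,
    committee: CommitteeResult,
) -> AgreementSummary:
    """Assemble the full selector-by-selector agreement matrix."""
    if model.pair_ids != choices.pair_ids:
        raise ValidationError("model selection must cover the design's pairs")
    if committee.selection.pair_ids != choices.pair_ids:
        raise ValidationError("committee must cover the design's pairs")
    answered = choices.choices != ChoiceMatrix.MISSING
    rater_vals = choices.choices.astype(float)
    vectors = [
        (rid, rater_vals[i], answered[i]) for i, rid in enumerate(choices.rater_ids)
    ]
    all_mask = np.ones(choices.n_pairs, dtype=bool)
    vectors.append((model.selector_id, model.values, all_mask))
    vectors.append(("committee", committee.selection.values, all_mask))

    k = len(vectors)
    mat = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            _, va, ma = vectors[a]
            _, vb, mb = vectors[b]
            both = ma & mb
            if not both.any():
                mat[a, b] = mat[b, a] = float("nan")
                continue
            mat[a, b] = mat[b, a] = _pairwise_agreement(va[both], vb[both])

    n_r = choices.n_raters
    rater_block = mat[:n_r, :n_r]
    iu = np.triu_indices(n_r, k=1)
    mean_rr = float(np.nanmean(rater_block[iu])) if n_r > 1 else float("nan")
    mean_mr = float(np.nanmean(mat[n_r, :n_r])) if n_r else float("nan")
    model_committee = float(mat[n_r, n_r + 1])
    # credit 1 - (committee correct while model incorrect), tie mass 0.5
    m, v = model.values, committee.selection.values
    agree_or_better = float(np.mean(1.0 - v * (1.0 - m)))
    return AgreementSummary(
        selector_ids=[name for name, _, _ in vectors],
        matrix=mat,
        mean_rater_rater=mean_rr,
        mean_model_rater=mean_mr,
        model_committee=model_committee,
        agree_or_better=agree_or_better,
    )


# --------------------------------------------------------------------------
# Experience correlation


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson and Spearman correlation of accuracy with experience."""

    pearson_r: float
    spearman_rho: float
    r_squared: float
    p_pearson: float
    p_spearman: float
    n: int
    undefined: bool = False


def experience_correlation(
    performances: Sequence[RaterPerformance],
    raters: Sequence[RaterRecord],
) -> CorrelationResult:
    """Correlate per-rater quiz accuracy with years of experience.

    Zero variance in either variable is flagged as undefined rather
    than reported as a zero correlation.
    """
    by_id = {r.rater_id: r.years_experience for r in raters}
    missing = [p.selector_id for p in performances if p.selector_id not in by_id]
    if missing:
        raise ValidationError(f"no experience record for rater(s): {missing}")
    years = np.array([by_id[p.selector_id] for p in performances])
    acc = np.array([p.accuracy for p in performances])
    if years.size < 3:
        raise ValidationError("need at least 3 raters for a correlation")
    if np.ptp(years) == 0 or np.ptp(acc) == 0:
        nan = float("nan")
        return CorrelationResult(nan, nan, nan, nan, nan, int(years.size), True)
    pearson = stats.pearsonr(years, acc)
    spearman = stats.spearmanr(years, acc)
    r = float(pearson.statistic)
    return CorrelationResult(
        pearson_r=r,
        spearman_rho=float(spearman.statistic),
        r_squared=r * r,
        p_pearson=float(pearson.pvalue),
        p_spearman=float(spearman.pvalue),
        n=int(years.size),
    )


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (optional; per-rater p-values are
    reported unadjusted by default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
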