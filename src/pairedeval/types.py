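"""Core record types shared across the package.

The evaluation design is a two-alternative forced-choice quiz: each item
(a *pair*) holds one embryo that led to a successful outcome and one that
did not, both from the same clinic.  A selector (an embryologist, the
scoring model, or the majority-vote committee) picks one embryo per pair;
picking the successful embryo counts as a correct answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "SchemaError",
    "EmbryoRecord",
    "RaterRecord",
    "PairRecord",
    "SelectionVector",
    "RaterPerformance",
    "ChoiceMatrix",
    "POSITIVE",
    "NEGATIVE",
]

POSITIVE = "positive"
NEGATIVE = "negative"

#: selection codes used in :class:`SelectionVector` values — because the
#: successful embryo is by construction the correct answer, the selection
#: value doubles as per-pair correctness (ties credited one half).
CHOSE_POSITIVE = 1.0
CHOSE_NEGATIVE = 0.0
TIE = 0.5


class ValidationError(ValueError):
    """A table or record violates a domain invariant."""


class SchemaError(ValidationError):
    """A table is missing a required column."""


@dataclass(frozen=True)
class EmbryoRecord:
    """One transferred embryo.

    Parameters
    ----------
    embryo_id
        Opaque unique identifier.
    clinic_id
        Stratum label; pairs are always formed within a clinic.
    outcome
        ``"positive"`` (pregnancy / live birth) or ``"negative"``
        (transferred without success).
    model_score
        Continuous selection score on an arbitrary monotone scale
        (0-10 in typical exports); ``None`` for rater-only analyses.
    """

    embryo_id: str
    clinic_id: str
    outcome: str
    model_score: float | None = None

    def __post_init__(self) -> None:
        if self.outcome not in (POSITIVE, NEGATIVE):
            raise ValidationError(
                f"embryo {self.embryo_id!r}: outcome must be "
                f"'positive' or 'negative', got {self.outcome!r}"
            )
        if self.model_score is not None and not np.isfinite(self.model_score):
            raise ValidationError(
                f"embryo {self.embryo_id!r}: model_score must be finite"
            )


@dataclass(frozen=True)
class RaterRecord:
    """A quiz participant with years of professional experience."""

    rater_id: str
    years_experience: float

    def __post_init__(self) -> None:
        if self.years_experience < 0:
            raise ValidationError(
                f"rater {self.rater_id!r}: years_experience must be >= 0"
            )


@dataclass(frozen=True)
class PairRecord:
    """One quiz item: a positive and a negative embryo from one clinic.

    ``first_displayed_embryo_id`` records which embryo is shown first
    (left) to raters; every statistic depends only on which embryo was
    chosen, never on display side.
    """

    pair_id: str
    clinic_id: str
    positive_embryo_id: str
    negative_embryo_id: str
    first_displayed_embryo_id: str = ""

    def __post_init__(self) -> None:
        if self.positive_embryo_id == self.negative_embryo_id:
            raise ValidationError(
                f"pair {self.pair_id!r}: the two embryos must differ"
            )
        if self.first_displayed_embryo_id and self.first_displayed_embryo_id not in (
            self.positive_embryo_id,
            self.negative_embryo_id,
        ):
            raise ValidationError(
                f"pair {self.pair_id!r}: first_displayed_embryo_id must be "
                "one of the pair's embryos"
            )

    @property
    def embryo_ids(self) -> tuple[str, str]:
        return (self.positive_embryo_id, self.negative_embryo_id)


@dataclass
class SelectionVector:
    """Per-pair selections of one selector.

    ``values[i]`` is 1.0 if the positive (successful) embryo of pair
    ``pair_ids[i]`` was chosen, 0.0 if the negative one was chosen, and
    0.5 for a score tie.  Ties are only legal for score-based selectors;
    raters must choose.
    """

    selector_id: str
    pair_ids: list[str]
    values: np.ndarray
    allow_ties: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.pair_ids) != self.values.shape[0]:
            raise ValidationError("pair_ids and values length mismatch")
        legal = {CHOSE_POSITIVE, CHOSE_NEGATIVE, TIE}
        bad = set(np.unique(self.values)) - legal
        if bad:
            raise ValidationError(f"illegal selection values: {sorted(bad)}")
        if not self.allow_ties and np.any(self.values == TIE):
            raise ValidationError(
                f"selector {self.selector_id!r} may not record ties"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @property
    def n_ties(self) -> int:
        return int(np.sum(self.values == TIE))

    def has_ties(self) -> bool:
        return bool(np.any(self.values == TIE))


@dataclass(frozen=True)
class RaterPerformance:
    """Quiz score of one selector: correct answers over answered pairs."""

    selector_id: str
    n_pairs: int
    n_correct: float  # ties credited 0.5
    accuracy: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct <= self.n_pairs):
            raise ValidationError("n_correct must lie in [0, n_pairs]")
        if abs(self.accuracy - self.n_correct / self.n_pairs) > 1e-12:
            raise ValidationError("accuracy must equal n_correct / n_pairs")


class ChoiceMatrix:
    """Raters x pairs matrix of forced choices.

    Entries are ``1`` (positive embryo chosen), ``0`` (negative chosen)
    or ``-1`` (missing).  Rater and pair order follow first appearance in
    the source table and are never reordered.
    """

    MISSING = -1

    def __init__(
        self,
        rater_ids: Sequence[str],
        pairs: Sequence[PairRecord],
        choices: np.ndarray,
        raters: Sequence[RaterRecord] | None = None,
    ) -> None:
        self.rater_ids = list(rater_ids)
        self.pairs = list(pairs)
        self.pair_ids = [p.pair_id for p in self.pairs]
        choices = np.asarray(choices, dtype=np.int8)
        if choices.shape != (len(self.rater_ids), len(self.pairs)):
            raise ValidationError(
                f"choices shape {choices.shape} does not match "
                f"({len(self.rater_ids)} raters, {len(self.pairs)} pairs)"
            )
        if not np.isin(choices, (1, 0, self.MISSING)).all():
            raise ValidationError("choice entries must be 1, 0 or -1")
        self.choices = choices
        self.raters = list(raters) if raters is not None else None

    @property
    def n_raters(self) -> int:
        return len(self.rater_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_responses(self) -> int:
        return int(np.sum(self.choices != self.MISSING))

    @property
    def n_missing(self) -> int:
        return self.n_raters * self.n_pairs - self.n_responses

    def rater_selection(self, rater_id: str) -> SelectionVector:
        """Selection vector of one rater over the pairs they answered."""
        row = self.choices[self.rater_ids.index(rater_id)]
        answered = row != self.MISSING
        return SelectionVector(
            selector_id=rater_id,
            pair_ids=[p for p, a in zip(self.pair_ids, answered) if a],
            values=row[answered].astype(float),
        )

    def chosen_embryo_id(self, i_rater: int, i_pair: int) -> str | None:
        c = self.choices[i_rater, i_pair]
        if c == self.MISSING:
            return None
        p = self.pairs[i_pair]
        return p.positive_embryo_id if c == 1 else p.negative_embryo_id


def truth_vector(pairs: Iterable[PairRecord]) -> Mapping[str, str]:
    """Map pair_id -> embryo_id of the correct (successful) side."""
    return {p.pair_id: p.positive_embryo_id for p in pairs}
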