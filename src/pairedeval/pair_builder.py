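"""Construction of same-clinic positive/negative quiz pairs.

Within each clinic the positive and negative embryos are matched
one-to-one by a seeded uniform random bijection; no covariate matching
is attempted.  A clinic with an excess of one outcome contributes
``min(#positive, #negative)`` pairs and the remainder is reported as
unpaired (a clinic lacking one outcome entirely yields zero pairs and a
warning, not an error).  Display order (which embryo a rater sees
first) is assigned by an independent seeded fair coin per pair and
never influences any statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import NEGATIVE, POSITIVE, EmbryoRecord, PairRecord

__all__ = ["PairingResult", "build_pairs", "randomize_display", "derive_seeds"]

logger = logging.getLogger(__name__)


@dataclass
class PairingResult:
    """Pairs plus the embryos that could not be matched, per clinic."""

    pairs: list[PairRecord]
    unpaired: list[EmbryoRecord]
    per_clinic: dict[str, int] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def derive_seeds(seed: int, n: int = 2) -> list[int]:
    """Derive independent child seeds from one top-level seed.

    Child ``k`` is the first 32-bit word generated by
    ``SeedSequence(seed).spawn()[k]``, so a single integer reproduces
    the whole design (pairing = child 0, display = child 1).
    """
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0]) for c in children]


def build_pairs(embryos: list[EmbryoRecord], seed: int) -> PairingResult:
    """Match positives to negatives within each clinic, at random.

    Clinics are processed in first-appearance order; within a clinic
    the positive list keeps input order and the negative list is
    permuted by a seeded uniform shuffle, giving a uniform random
    bijection.  Pair ids are ``P0001, P0002, ...`` in assignment order.
    """
    rng = np.random.default_rng(seed)
    clinic_order: list[str] = []
    by_clinic: dict[str, dict[str, list[EmbryoRecord]]] = {}
    for e in embryos:
        if e.clinic_id not in by_clinic:
            by_clinic[e.clinic_id] = {POSITIVE: [], NEGATIVE: []}
            clinic_order.append(e.clinic_id)
        by_clinic[e.clinic_id][e.outcome].append(e)

    pairs: list[PairRecord] = []
    unpaired: list[EmbryoRecord] = []
    per_clinic: dict[str, int] = {}
    counter = 0
    for clinic in clinic_order:
        pos = by_clinic[clinic][POSITIVE]
        neg = by_clinic[clinic][NEGATIVE]
        n = min(len(pos), len(neg))
        per_clinic[clinic] = n
        if n == 0:
            logger.warning(
                "clinic %r has %d positive and %d negative embryos; no pairs formed",
                clinic, len(pos), len(neg),
            )
        perm = rng.permutation(len(neg))
        for k in range(n):
            counter += 1
            pairs.append(
                PairRecord(
                    pair_id=f"P{counter:04d}",
                    clinic_id=clinic,
                    positive_embryo_id=pos[k].embryo_id,
                    negative_embryo_id=neg[perm[k]].embryo_id,
                )
            )
        unpaired.extend(pos[n:])
        unpaired.extend(neg[perm[k2]] for k2 in range(n, len(neg)))
    return PairingResult(pairs=pairs, unpaired=unpaired, per_clinic=per_clinic)


def randomize_display(pairs: list[PairRecord], seed: int) -> list[PairRecord]:
    """Assign display order by an independent fair coin per pair."""
    rng = np.random.default_rng(seed)
    coins = rng.integers(0, 2, size=len(pairs))
    return [
        PairRecord(
            pair_id=p.pair_id,
            clinic_id=p.clinic_id,
            positive_embryo_id=p.positive_embryo_id,
            negative_embryo_id=p.negative_embryo_id,
            first_displayed_embryo_id=(
                p.positive_embryo_id if c == 1 else p.negative_embryo_id
            ),
        )
        for p, c in zip(pairs, coins)
    ]
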