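"""Readers and writers for the delimited tables and the JSON report.

All tables are plain delimited text with a header row (comma by default,
tab via ``delimiter="\t"``).  Readers validate every row against the
domain invariants and preserve row order; they never silently drop or
impute.  Missing responses are recorded as missing in the
:class:`~pairedeval.types.ChoiceMatrix` and handled downstream by
per-rater denominators.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    NEGATIVE,
    POSITIVE,
    ChoiceMatrix,
    EmbryoRecord,
    PairRecord,
    RaterRecord,
    SchemaError,
    ValidationError,
)

__all__ = [
    "read_embryo_table",
    "write_embryo_table",
    "read_pair_table",
    "write_pair_table",
    "read_rater_table",
    "write_rater_table",
    "read_response_table",
    "write_response_table",
    "write_report",
    "read_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1.0"

# accepted outcome spellings, case-insensitive
_POSITIVE_SYNONYMS = frozenset({"positive", "pos", "1", "true", "yes"})
_NEGATIVE_SYNONYMS = frozenset({"negative", "neg", "0", "false", "no"})


def _normalize_outcome(
    raw: str,
    positive_synonyms: frozenset[str] = _POSITIVE_SYNONYMS,
    negative_synonyms: frozenset[str] = _NEGATIVE_SYNONYMS,
) -> str:
    token = str(raw).strip().lower()
    if token in positive_synonyms:
        return POSITIVE
    if token in negative_synonyms:
        return NEGATIVE
    raise ValidationError(
        f"unrecognized outcome {raw!r}; accepted (case-insensitive): "
        f"{sorted(positive_synonyms)} or {sorted(negative_synonyms)}"
    )


def _read_table(path: str | Path, columns: Sequence[str], delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def _check_unique(values: pd.Series, what: str) -> None:
    dup = values[values.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate {what}: {sorted(set(dup))}")


def read_embryo_table(path: str | Path, delimiter: str = ",") -> list[EmbryoRecord]:
    """Read embryos from ``embryo_id,clinic_id,outcome[,model_score]``.

    Row order is preserved and the record count equals the data-line
    count; any invariant violation raises instead of skipping rows.
    """
    df = _read_table(path, ["embryo_id", "clinic_id", "outcome"], delimiter)
    _check_unique(df["embryo_id"], "embryo_id")
    records = []
    for row in df.itertuples(index=False):
        score_raw = getattr(row, "model_score", "")
        score = None if str(score_raw).strip() == "" else float(score_raw)
        records.append(
            EmbryoRecord(
                embryo_id=row.embryo_id,
                clinic_id=row.clinic_id,
                outcome=_normalize_outcome(row.outcome),
                model_score=score,
            )
        )
    return records


def write_embryo_table(
    embryos: Iterable[EmbryoRecord], path: str | Path, delimiter: str = ","
) -> None:
    embryos = list(embryos)
    df = pd.DataFrame(
        {
            "embryo_id": [e.embryo_id for e in embryos],
            "clinic_id": [e.clinic_id for e in embryos],
            "outcome": [e.outcome for e in embryos],
            "model_score": [
                "" if e.model_score is None else repr(float(e.model_score))
                for e in embryos
            ],
        }
    )
    df.to_csv(path, sep=delimiter, index=False)


def read_pair_table(path: str | Path, delimiter: str = ",") -> list[PairRecord]:
    df = _read_table(
        path,
        [
            "pair_id",
            "clinic_id",
            "positive_embryo_id",
            "negative_embryo_id",
            "first_displayed_embryo_id",
        ],
        delimiter,
    )
    _check_unique(df["pair_id"], "pair_id")
    return [
        PairRecord(
            pair_id=r.pair_id,
            clinic_id=r.clinic_id,
            positive_embryo_id=r.positive_embryo_id,
            negative_embryo_id=r.negative_embryo_id,
            first_displayed_embryo_id=r.first_displayed_embryo_id,
        )
        for r in df.itertuples(index=False)
    ]


def write_pair_table(
    pairs: Iterable[PairRecord], path: str | Path, delimiter: str = ","
) -> None:
    pairs = list(pairs)
    pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "clinic_id": [p.clinic_id for p in pairs],
            "positive_embryo_id": [p.positive_embryo_id for p in pairs],
            "negative_embryo_id": [p.negative_embryo_id for p in pairs],
            "first_displayed_embryo_id": [p.first_displayed_embryo_id for p in pairs],
        }
    ).to_csv(path, sep=delimiter, index=False)


def read_rater_table(path: str | Path, delimiter: str = ",") -> list[RaterRecord]:
    df = _read_table(path, ["rater_id", "years_experience"], delimiter)
    _check_unique(df["rater_id"], "rater_id")
    return [
        RaterRecord(rater_id=r.rater_id, years_experience=float(r.years_experience))
        for r in df.itertuples(index=False)
    ]


def write_rater_table(
    raters: Iterable[RaterRecord], path: str | Path, delimiter: str = ","
) -> None:
    raters = list(raters)
    pd.DataFrame(
        {
            "rater_id": [r.rater_id for r in raters],
            "years_experience": [repr(float(r.years_experience)) for r in raters],
        }
    ).to_csv(path, sep=delimiter, index=False)


def read_response_table(
    path: str | Path,
    pairs: Sequence[PairRecord],
    raters: Sequence[RaterRecord] | None = None,
    delimiter: str = ",",
) -> ChoiceMatrix:
    """Read ``rater_id,pair_id,chosen_embryo_id`` into a choice matrix.

    Raters and pairs keep first-appearance order (pair order is taken
    from ``pairs``).  A chosen embryo that does not belong to the named
    pair, an unknown pair, or a duplicate (rater, pair) row raises a
    :class:`ValidationError` identifying the offending row.  Pairs a
    rater never answered are flagged missing, never imputed.
    """
    df = _read_table(path, ["rater_id", "pair_id", "chosen_embryo_id"], delimiter)
    pair_index = {p.pair_id: i for i, p in enumerate(pairs)}
    pair_by_id = {p.pair_id: p for p in pairs}

    rater_ids: list[str] = []
    rater_index: dict[str, int] = {}
    for rid in df["rater_id"]:
        if rid not in rater_index:
            rater_index[rid] = len(rater_ids)
            rater_ids.append(rid)

    choices = np.full((len(rater_ids), len(pairs)), ChoiceMatrix.MISSING, dtype=np.int8)
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.pair_id not in pair_index:
            raise ValidationError(
                f"line {line_no}: unknown pair_id {row.pair_id!r}"
            )
        pair = pair_by_id[row.pair_id]
        if row.chosen_embryo_id == pair.positive_embryo_id:
            code = 1
        elif row.chosen_embryo_id == pair.negative_embryo_id:
            code = 0
        else:
            raise ValidationError(
                f"line {line_no}: embryo {row.chosen_embryo_id!r} does not "
                f"belong to pair {row.pair_id!r}"
            )
        i, j = rater_index[row.rater_id], pair_index[row.pair_id]
        if choices[i, j] != ChoiceMatrix.MISSING:
            raise ValidationError(
                f"line {line_no}: duplicate response for "
                f"(rater {row.rater_id!r}, pair {row.pair_id!r})"
            )
        choices[i, j] = code

    ordered_raters = None
    if raters is not None:
        by_id = {r.rater_id: r for r in raters}
        unknown = [rid for rid in rater_ids if rid not in by_id]
        if unknown:
            raise ValidationError(f"responses from unknown rater(s): {unknown}")
        ordered_raters = [by_id[rid] for rid in rater_ids]
    return ChoiceMatrix(rater_ids, list(pairs), choices, raters=ordered_raters)


def write_response_table(
    choices: ChoiceMatrix, path: str | Path, delimiter: str = ","
) -> None:
    rows = {"rater_id": [], "pair_id": [], "chosen_embryo_id": []}
    for i, rid in enumerate(choices.rater_ids):
        for j, pid in enumerate(choices.pair_ids):
            chosen = choices.chosen_embryo_id(i, j)
            if chosen is None:
                continue
            rows["rater_id"].append(rid)
            rows["pair_id"].append(pid)
            rows["chosen_embryo_id"].append(chosen)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_report(results: Mapping[str, Any], path: str | Path) -> None:
    """Write the aggregated analysis report as JSON.

    Key order follows insertion order of ``results`` (stable), a schema
    version is always present under ``meta``, and the same results
    always serialize to identical bytes.
    """
    doc = dict(results)
    meta = dict(doc.get("meta", {}))
    meta.setdefault("schema_version", REPORT_SCHEMA_VERSION)
    doc["meta"] = meta
    for key in ("per_rater", "mcnemar", "committee", "agreement", "subgroups",
                "correlation"):
        doc.setdefault(key, None)
    text = json.dumps(_jsonify(doc), indent=2, allow_nan=False)
    Path(path).write_text(text + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
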