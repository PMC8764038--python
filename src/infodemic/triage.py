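"""Rule-based COVID-19 suspect-case triage over a 7-item questionnaire.

The classifier applies the WHO Interim Guidance surveillance case definitions
to seven boolean answers: 14-day travel history to an area with community
transmission, 14-day close contact with a confirmed/probable case, fever,
cough, shortness of breath (SOB), need for hospitalization, and presence of
an alternative diagnosis fully explaining the presentation.

Definition A: acute respiratory illness (fever AND cough-or-SOB) plus travel
history.  Definition B: any acute respiratory illness (fever OR cough OR SOB
— "ARI" interpreted as any of the three, isolated in one predicate) plus
close contact.  Definition C: severe acute respiratory illness (fever AND
cough-or-SOB) requiring hospitalization, with no alternative diagnosis.
A respondent is a suspect case iff any definition fires.

Cohort percentages are truncated (not rounded) to two decimals, the
convention the printed marginals follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class InputError(ValueError):
    """Empty cohort or malformed response table."""


FIELD_ORDER = (
    "travel_history_14d",
    "close_contact_14d",
    "fever",
    "cough",
    "sob",
    "hospitalization_required",
    "alternate_diagnosis",
)


@dataclass(frozen=True)
class TriageResponse:
    """The seven forced-choice boolean answers of one respondent."""

    travel_history_14d: bool
    close_contact_14d: bool
    fever: bool
    cough: bool
    sob: bool
    hospitalization_required: bool
    alternate_diagnosis: bool

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (bool,)):
                raise InputError(f"field {f.name!r} must be a boolean, got {v!r}")


@dataclass(frozen=True)
class TriageResult:
    """Satisfied case definitions; suspect iff any definition fires."""

    categories: frozenset[str]
    is_suspect: bool

    def __post_init__(self) -> None:
        if self.is_suspect != bool(self.categories):
            raise ValueError("is_suspect must mirror non-empty categories")


def _respiratory_sign(r: TriageResponse) -> bool:
    return r.cough or r.sob


def _any_ari(r: TriageResponse) -> bool:
    """'Any acute respiratory illness' of definition B: fever OR cough OR SOB.

    Kept as one predicate so the interpretation can be changed in one place.
    """
    return r.fever or r.cough or r.sob


def classify(r: TriageResponse) -> TriageResult:
    """Apply suspect-case definitions A/B/C to one response."""
    categories = set()
    if r.fever and _respiratory_sign(r) and r.travel_history_14d:
        categories.add("A")
    if _any_ari(r) and r.close_contact_14d:
        categories.add("B")
    if (r.fever and _respiratory_sign(r) and r.hospitalization_required
            and not r.alternate_diagnosis):
        categories.add("C")
    return TriageResult(categories=frozenset(categories),
                        is_suspect=bool(categories))


def truncate_pct(count: int, n_total: int) -> float:
    """Percentage truncated (floored) to two decimals."""
    return math.floor(100.0 * count / n_total * 100.0) / 100.0


@dataclass
class CohortSummary:
    """Cohort size, suspect count, and per-item counts with truncated percentages."""

    n_total: int
    n_suspect: int
    item_counts: dict[str, int]
    item_percentages: dict[str, float]
    suspect_percentage: float


def summarize_cohort(responses: Sequence[TriageResponse]) -> CohortSummary:
    """Tally per-item positives and suspect cases over a cohort."""
    if not responses:
        raise InputError("cohort must be non-empty")
    n = len(responses)
    counts = {f: sum(getattr(r, f) for r in responses) for f in FIELD_ORDER}
    n_suspect = sum(classify(r).is_suspect for r in responses)
    return CohortSummary(
        n_total=n,
        n_suspect=n_suspect,
        item_counts=counts,
        item_percentages={f: truncate_pct(c, n) for f, c in counts.items()},
        suspect_percentage=truncate_pct(n_suspect, n),
    )


_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f"}


def _parse_bool(value: object, field_name: str, row: int) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise InputError(f"row {row}: field {field_name!r}: "
                     f"cannot parse boolean from {value!r}")


def read_responses_csv(path: str | Path) -> list[TriageResponse]:
    """Read responses from a CSV with the seven boolean columns of FIELD_ORDER."""
    df = pd.read_csv(path)
    missing = [f for f in FIELD_ORDER if f not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        out.append(TriageResponse(**{
            f: _parse_bool(rec[f], f, i) for f in FIELD_ORDER
        }))
    return out


def write_responses_csv(responses: Iterable[TriageResponse],
                        path: str | Path) -> None:
    pd.DataFrame(
        [{f: int(getattr(r, f)) for f in FIELD_ORDER} for r in responses]
    ).to_csv(path, index=False)
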