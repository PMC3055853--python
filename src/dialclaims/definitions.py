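"""The four outpatient-claims case definitions for chronic dialysis.

Each definition is a pure predicate over a patient's set of distinct
outpatient dialysis claim *days* within the observation window:

* ``ONE_CLAIM``        — at least 1 outpatient claim
* ``TWO_CLAIMS``       — at least 2 outpatient claims (distinct days)
* ``TWO_CLAIMS_90D``   — at least 2 outpatient claims at least 90 days apart
* ``CONTINUOUS_90D``   — continuous outpatient claims spanning at least
  90 days with no gap between successive claims greater than 21 days

Counting conventions (fixed here, applied everywhere): claims are counted
as distinct claim days per patient, so two billings on one day do not
satisfy the two-claim rule; "at least 90 days apart" is inclusive
(difference >= 90 days); "gap greater than 21 days" is strict (a gap of
exactly 21 days does not break a run); day differences are exact
calendar-day counts.

The cohort-entry index date is the second distinct claim day, falling
back to the first (and only) claim day for single-claim positives under
the one-claim definition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date
from typing import Callable, Iterable, Mapping

from .exceptions import ContractError
from .io import Claim, ObservationWindow

#: Minimum span, in days, between earliest and latest qualifying claim.
SPAN_DAYS = 90
#: Largest allowed gap, in days, between successive claims in a run.
MAX_GAP_DAYS = 21


class Definition(str, enum.Enum):
    """Identifier of one of the four claims-based case definitions."""

    ONE_CLAIM = "d1"
    TWO_CLAIMS = "d2"
    TWO_CLAIMS_90D = "d3"
    CONTINUOUS_90D = "d4"

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    Definition.ONE_CLAIM: "1 outpatient claim",
    Definition.TWO_CLAIMS: "2 outpatient claims",
    Definition.TWO_CLAIMS_90D: "2 outpatient claims at least 90 days apart",
    Definition.CONTINUOUS_90D: (
        "Continuous outpatient claims for at least 90 days "
        "with no gaps greater than 21 days"
    ),
}

ALL_DEFINITIONS = tuple(Definition)


@dataclass(frozen=True)
class ClaimDaySeries:
    """Per-patient strictly increasing sequence of distinct claim days."""

    patient_id: str
    dates: tuple[date, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.dates)


@dataclass(frozen=True)
class ClassificationResult:
    """Patients positive under one definition, with their index dates."""

    definition: Definition
    positives: frozenset[str]
    index_dates: Mapping[str, date]


def to_day_series(
    claims: Iterable[Claim], window: ObservationWindow | None = None
) -> list[ClaimDaySeries]:
    """Collapse claims to one entry per patient per calendar day.

    Claims must already be filtered to outpatient dialysis codes; if a
    window is given, claim dates outside it are rejected.
    """
    by_patient: dict[str, set[date]] = {}
    for claim in claims:
        if window is not None and claim.service_date not in window:
            raise ValueError(
                f"claim for {claim.patient_id} on {claim.service_date} "
                f"is outside the observation window"
            )
        by_patient.setdefault(claim.patient_id, set()).add(claim.service_date)
    return [
        ClaimDaySeries(pid, tuple(sorted(days)))
        for pid, days in sorted(by_patient.items())
    ]


def classify_d1(series: ClaimDaySeries) -> bool:
    """At least 1 outpatient claim."""
    return len(series.dates) >= 1


def classify_d2(series: ClaimDaySeries) -> bool:
    """At least 2 outpatient claims on distinct days."""
    return len(series.dates) >= 2


def classify_d3(series: ClaimDaySeries) -> bool:
    """At least 2 outpatient claims at least 90 days apart (inclusive)."""
    if len(series.dates) < 2:
        return False
    return (series.dates[-1] - series.dates[0]).days >= SPAN_DAYS


def classify_d4(series: ClaimDaySeries) -> bool:
    """Continuous claims spanning >= 90 days with no gap > 21 days.

    True iff some maximal run of claim days, within which every successive
    gap is <= 21 days, spans at least 90 days end to end. The run need not
    start at the first claim.
    """
    run_start = 0
    for i in range(1, len(series.dates)):
        if (series.dates[i] - series.dates[i - 1]).days > MAX_GAP_DAYS:
            if (series.dates[i - 1] - series.dates[run_start]).days >= SPAN_DAYS:
                return True
            run_start = i
    if not series.dates:
        return False
    return (series.dates[-1] - series.dates[run_start]).days >= SPAN_DAYS


CLASSIFIERS: Mapping[Definition, Callable[[ClaimDaySeries], bool]] = {
    Definition.ONE_CLAIM: classify_d1,
    Definition.TWO_CLAIMS: classify_d2,
    Definition.TWO_CLAIMS_90D: classify_d3,
    Definition.CONTINUOUS_90D: classify_d4,
}


def classify(series: ClaimDaySeries, definition: Definition) -> bool:
    return CLASSIFIERS[definition](series)


def assign_index_date(series: ClaimDaySeries, definition: Definition) -> date:
    """Cohort-entry date: the second distinct claim day.

    Single-claim positives (possible only under the one-claim definition)
    enter on their first and only claim day.
    """
    if not classify(series, definition):
        raise ContractError(
            f"patient {series.patient_id} is not positive under {definition.value}"
        )
    return series.dates[1] if len(series.dates) >= 2 else series.dates[0]


def classify_cohort(
    series_collection: Iterable[ClaimDaySeries],
    definition: Definition,
    window: ObservationWindow | None = None,
) -> ClassificationResult:
    """Apply one definition to every patient series."""
    positives: set[str] = set()
    index_dates: dict[str, date] = {}
    for series in series_collection:
        if classify(series, definition):
            positives.add(series.patient_id)
            idx = assign_index_date(series, definition)
            if window is not None and idx not in window:
                raise ValueError(
                    f"index date {idx} for {series.patient_id} outside window"
                )
            index_dates[series.patient_id] = idx
    return ClassificationResult(definition, frozenset(positives), index_dates)
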