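"""Domain types and delimited-text I/O for claims, registry, and attributes.

File layouts (all UTF-8, comma-separated, ISO-8601 dates):

* claims:      ``patient_id,service_date,procedure_code,setting``
* registry:    ``patient_id,start_date``
* attributes:  ``patient_id,birth_year,sex``
* population:  ``patient_id`` (one id per row; used to pin the study N)

``read_claims`` applies the study filters at read time: only outpatient
claims whose procedure code is in the configured dialysis code set and
whose service date falls inside the closed observation window are kept,
and byte-identical duplicates (same patient, date, and code — e.g.
resubmitted billings) are collapsed to one.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .codes import CCP_DIALYSIS, CodeSet
from .exceptions import FormatError, RowError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

CLAIMS_COLUMNS = ("patient_id", "service_date", "procedure_code", "setting")
REGISTRY_COLUMNS = ("patient_id", "start_date")
ATTRIBUTES_COLUMNS = ("patient_id", "birth_year", "sex")


class Setting(str, enum.Enum):
    """Care setting of a physician claim."""

    OUTPATIENT = "outpatient"
    INPATIENT = "inpatient"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


@dataclass(frozen=True, order=True)
class Claim:
    """One outpatient physician billing record."""

    patient_id: str
    service_date: date
    procedure_code: str
    setting: Setting = Setting.OUTPATIENT

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.procedure_code:
            raise ValueError("procedure_code must be non-empty")
        if not isinstance(self.setting, Setting):
            object.__setattr__(self, "setting", Setting(self.setting))


@dataclass(frozen=True, order=True)
class RegistryRecord:
    """Reference-standard chronic-dialysis registry entry.

    ``start_date`` is the first dialysis for ESRD, or the date a
    nephrologist deemed dialysis chronic for a patient who started
    dialysis for acute kidney injury.
    """

    patient_id: str
    start_date: date

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


@dataclass(frozen=True)
class ObservationWindow:
    """Closed calendar interval [start, end] over which claims count."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window start {self.start} is after end {self.end}")

    def __contains__(self, day: date) -> bool:
        return self.start <= day <= self.end

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


#: The study's calendar-year 2008 window.
WINDOW_2008 = ObservationWindow(date(2008, 1, 1), date(2008, 12, 31))


@dataclass(frozen=True)
class PatientAttributes:
    patient_id: str
    birth_year: int | None = None
    sex: Sex = Sex.UNKNOWN

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


def _read_table(path: PathLike, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (expected header {','.join(columns)})")
    got = list(frame.columns)
    missing = [c for c in columns if c not in got]
    extra = [c for c in got if c not in columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if extra:
        raise FormatError(f"{path}: unexpected column(s): {', '.join(extra)}")
    return frame[list(columns)]


def _parse_date(value: str, line: int, column: str) -> date:
    try:
        return datetime.strptime(value, "%Y-%m-%d").date()
    except ValueError:
        raise RowError(f"unparseable {column} {value!r} (expected YYYY-MM-DD)", line)


def read_claims(
    path: PathLike,
    code_set: CodeSet = CCP_DIALYSIS,
    window: ObservationWindow = WINDOW_2008,
) -> list[Claim]:
    """Read a claims file, keeping outpatient dialysis claims in ``window``.

    Inpatient claims are discarded with a logged count; exact duplicates
    (patient, date, code) collapse to one claim. The result is sorted, so
    re-reading serialized output yields an identical collection.
    """
    frame = _read_table(path, CLAIMS_COLUMNS)
    kept: set[Claim] = set()
    n_inpatient = 0
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # header is line 1
        service_date = _parse_date(row.service_date, line, "service_date")
        try:
            setting = Setting(row.setting)
        except ValueError:
            raise RowError(
                f"invalid setting {row.setting!r} (expected 'outpatient' or 'inpatient')",
                line,
            )
        if setting is Setting.INPATIENT:
            n_inpatient += 1
            continue
        if row.procedure_code not in code_set or service_date not in window:
            continue
        kept.add(Claim(row.patient_id, service_date, row.procedure_code, setting))
    if n_inpatient:
        logger.info("discarded %d inpatient claim(s)", n_inpatient)
    logger.info("retained %d outpatient dialysis claim(s) from %s", len(kept), path)
    return sorted(kept)


def read_registry(path: PathLike) -> list[RegistryRecord]:
    """Read the reference-standard registry; earliest start wins on duplicates."""
    frame = _read_table(path, REGISTRY_COLUMNS)
    earliest: dict[str, date] = {}
    for i, row in enumerate(frame.itertuples(index=False)):
        start = _parse_date(row.start_date, i + 2, "start_date")
        if row.patient_id in earliest:
            logger.warning(
                "duplicate registry entry for %s; keeping earliest start date",
                row.patient_id,
            )
            earliest[row.patient_id] = min(earliest[row.patient_id], start)
        else:
            earliest[row.patient_id] = start
    return sorted(RegistryRecord(pid, start) for pid, start in earliest.items())


def read_attributes(path: PathLike) -> list[PatientAttributes]:
    """Read optional patient attributes (birth year, sex); blanks allowed."""
    frame = _read_table(path, ATTRIBUTES_COLUMNS)
    out: list[PatientAttributes] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2
        birth_year: int | None = None
        if row.birth_year.strip():
            try:
                birth_year = int(row.birth_year)
            except ValueError:
                raise RowError(f"unparseable birth_year {row.birth_year!r}", line)
        sex = Sex.UNKNOWN
        if row.sex.strip():
            try:
                sex = Sex(row.sex)
            except ValueError:
                raise RowError(
                    f"invalid sex {row.sex!r} (expected male/female/unknown)", line
                )
        out.append(PatientAttributes(row.patient_id, birth_year, sex))
    return out


def read_population(path: PathLike) -> set[str]:
    """Read an explicit study-population file (one patient_id per row)."""
    frame = _read_table(path, ("patient_id",))
    return set(frame["patient_id"])


def write_claims(claims: Iterable[Claim], path: PathLike) -> None:
    frame = pd.DataFrame(
        [
            (c.patient_id, c.service_date.isoformat(), c.procedure_code, c.setting.value)
            for c in sorted(claims)
        ],
        columns=list(CLAIMS_COLUMNS),
    )
    frame.to_csv(path, index=False)


def write_registry(records: Iterable[RegistryRecord], path: PathLike) -> None:
    frame = pd.DataFrame(
        [(r.patient_id, r.start_date.isoformat()) for r in sorted(records)],
        columns=list(REGISTRY_COLUMNS),
    )
    frame.to_csv(path, index=False)
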