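"""End-to-end validation of claims case definitions against a registry.

``ClaimsValidation`` is a model-style object: construct it from in-memory
collections, data frames, or files, then call :meth:`ClaimsValidation.fit`
to obtain a :class:`ValidationResults` carrying one agreement report per
requested definition, per-definition cohort summaries, index-date
assignments, and a ``summary()`` text table.

The study population defaults to every patient id seen in any input
(claims, registry, attributes). The original study's population was a
laboratory cohort (everyone with an outpatient serum creatinine), which
cannot be reconstructed from claims alone, so the true-negative cell d —
and with it kappa and prevalence — depends on the supplied population.
Pass ``population`` (explicit ids) or ``population_size`` (total N; the
difference pads d with anonymous true negatives) to pin N exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import (
    AgreementReport,
    TwoByTwo,
    format_report_table,
    report,
    reports_to_frame,
    round_half_up,
)
from .codes import CCP_DIALYSIS, CodeSet
from .definitions import (
    ALL_DEFINITIONS,
    ClaimDaySeries,
    ClassificationResult,
    Definition,
    classify_cohort,
    to_day_series,
)
from .io import (
    Claim,
    ObservationWindow,
    PathLike,
    PatientAttributes,
    RegistryRecord,
    Setting,
    Sex,
    read_attributes,
    read_claims,
    read_population,
    read_registry,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSummary:
    """Basic characteristics of one definition's positive cohort."""

    definition: Definition
    n: int
    mean_age: float | None = None
    sd_age: float | None = None
    pct_male: float | None = None
    median_claim_days: float | None = None
    iqr_claim_days: tuple[float, float] | None = None


def summarize_cohort(
    positives: Iterable[str],
    attributes: Mapping[str, PatientAttributes] | None,
    series_by_patient: Mapping[str, ClaimDaySeries],
    definition: Definition,
    reference_year: int,
) -> CohortSummary:
    """Cohort size, age, sex, and claim-day statistics for the positives.

    Patients missing an attribute are excluded from that statistic only;
    the exclusion count is logged.
    """
    ids = sorted(positives)
    n = len(ids)
    mean_age = sd_age = pct_male = None
    if attributes is not None and n:
        ages = [
            reference_year - attributes[p].birth_year
            for p in ids
            if p in attributes and attributes[p].birth_year is not None
        ]
        if len(ages) < n:
            logger.info(
                "%s: %d patient(s) missing birth year excluded from age summary",
                definition.value,
                n - len(ages),
            )
        if ages:
            mean_age = float(np.mean(ages))
            sd_age = float(np.std(ages, ddof=1)) if len(ages) > 1 else 0.0
        sexes = [
            attributes[p].sex
            for p in ids
            if p in attributes and attributes[p].sex is not Sex.UNKNOWN
        ]
        if sexes:
            pct_male = 100.0 * sum(s is Sex.MALE for s in sexes) / len(sexes)
    median_days = iqr = None
    if n:
        counts = [len(series_by_patient[p].dates) for p in ids]
        median_days = float(np.median(counts))
        q1, q3 = np.percentile(counts, [25, 75])
        iqr = (float(q1), float(q3))
    return CohortSummary(definition, n, mean_age, sd_age, pct_male, median_days, iqr)


class ClaimsValidation:
    """Agreement of claims-based chronic-dialysis definitions with a registry.

    Parameters
    ----------
    claims
        Outpatient dialysis claims, already filtered to the code set and
        window (as ``read_claims`` returns them).
    registry
        Reference-standard registry records. A record counts as a registry
        positive if its start date is on or before the window end.
    window
        Closed observation interval for claims and index dates.
    population, population_size
        Optional explicit study population (ids) and/or total N. When
        ``population_size`` exceeds the ids actually seen, the remainder
        enters the true-negative cell d.
    attributes
        Optional patient attributes for cohort summaries.
    definitions
        Which case definitions to evaluate (default: all four).
    """

    def __init__(
        self,
        claims: Sequence[Claim],
        registry: Sequence[RegistryRecord],
        window: ObservationWindow,
        *,
        population: Iterable[str] | None = None,
        population_size: int | None = None,
        attributes: Sequence[PatientAttributes] | None = None,
        definitions: Sequence[Definition] = ALL_DEFINITIONS,
    ):
        if not definitions:
            raise ValueError("at least one definition is required")
        self.claims = list(claims)
        self.registry = list(registry)
        self.window = window
        self.definitions = tuple(definitions)
        self.attributes = (
            {a.patient_id: a for a in attributes} if attributes is not None else None
        )

        ids = {c.patient_id for c in self.claims}
        ids |= {r.patient_id for r in self.registry}
        if self.attributes:
            ids |= set(self.attributes)
        if population is not None:
            ids |= set(population)
        if not ids:
            raise ValueError("empty study population: no patients in any input")
        self.population: frozenset[str] = frozenset(ids)
        if population_size is not None:
            if population_size < len(self.population):
                raise ValueError(
                    f"population_size {population_size} is smaller than the "
                    f"{len(self.population)} patient ids actually observed"
                )
            self.population_size = population_size
        else:
            self.population_size = len(self.population)
        logger.info(
            "population: %d ids observed, N = %d", len(self.population), self.population_size
        )

    @classmethod
    def from_files(
        cls,
        claims_path: PathLike,
        registry_path: PathLike,
        window: ObservationWindow,
        *,
        attributes_path: PathLike | None = None,
        population_path: PathLike | None = None,
        population_size: int | None = None,
        code_set: CodeSet = CCP_DIALYSIS,
        definitions: Sequence[Definition] = ALL_DEFINITIONS,
    ) -> "ClaimsValidation":
        claims = read_claims(claims_path, code_set, window)
        registry = read_registry(registry_path)
        attributes = read_attributes(attributes_path) if attributes_path else None
        population = read_population(population_path) if population_path else None
        return cls(
            claims,
            registry,
            window,
            population=population,
            population_size=population_size,
            attributes=attributes,
            definitions=definitions,
        )

    @classmethod
    def from_dataframes(
        cls,
        claims: pd.DataFrame,
        registry: pd.DataFrame,
        window: ObservationWindow,
        *,
        code_set: CodeSet = CCP_DIALYSIS,
        **kwargs,
    ) -> "ClaimsValidation":
        """Build from data frames with the documented file columns."""

        def _date(v) -> date:
            return v if isinstance(v, date) else date.fromisoformat(str(v))

        claim_objs = [
            Claim(str(r.patient_id), _date(r.service_date), str(r.procedure_code),
                  Setting(getattr(r, "setting", "outpatient")))
            for r in claims.itertuples(index=False)
        ]
        claim_objs = [
            c
            for c in claim_objs
            if c.setting is Setting.OUTPATIENT
            and c.procedure_code in code_set
            and c.service_date in window
        ]
        registry_objs = [
            RegistryRecord(str(r.patient_id), _date(r.start_date))
            for r in registry.itertuples(index=False)
        ]
        return cls(sorted(set(claim_objs)), registry_objs, window, **kwargs)

    @property
    def registry_positives(self) -> frozenset[str]:
        return frozenset(
            r.patient_id for r in self.registry if r.start_date <= self.window.end
        )

    def fit(self, include_negative_measures: bool = False) -> "ValidationResults":
        """Classify the cohort under each definition and score agreement."""
        series = to_day_series(self.claims, self.window)
        series_by_patient = {s.patient_id: s for s in series}
        registry_pos = self.registry_positives
        logger.info(
            "claims: %d; patients with >= 1 claim day: %d; registry positives: %d",
            len(self.claims),
            len(series),
            len(registry_pos),
        )

        classifications: dict[Definition, ClassificationResult] = {}
        reports: dict[Definition, AgreementReport] = {}
        tables: dict[Definition, TwoByTwo] = {}
        summaries: dict[Definition, CohortSummary] = {}
        pad = self.population_size - len(self.population)
        for definition in self.definitions:
            result = classify_cohort(series, definition, self.window)
            classifications[definition] = result
            a = len(result.positives & registry_pos)
            b = len(result.positives - registry_pos)
            c = len(registry_pos - result.positives)
            d = len(self.population) - a - b - c + pad
            table = TwoByTwo(a, b, c, d)
            tables[definition] = table
            reports[definition] = report(
                definition,
                table,
                include_negative=include_negative_measures,
                strict=False,
            )
            summaries[definition] = summarize_cohort(
                result.positives,
                self.attributes,
                series_by_patient,
                definition,
                self.window.end.year,
            )
            logger.info(
                "%s: %d positives (a=%d b=%d c=%d d=%d)",
                definition.value, a + b, a, b, c, d,
            )
        return ValidationResults(self, classifications, tables, reports, summaries)


class ValidationResults:
    """Fitted agreement statistics for every requested definition."""

    def __init__(
        self,
        model: ClaimsValidation,
        classifications: Mapping[Definition, ClassificationResult],
        tables: Mapping[Definition, TwoByTwo],
        reports: Mapping[Definition, AgreementReport],
        cohort_summaries: Mapping[Definition, CohortSummary],
    ):
        self.model = model
        self.classifications = dict(classifications)
        self.tables = dict(tables)
        self.reports = dict(reports)
        self.cohort_summaries = dict(cohort_summaries)

    @property
    def registry_prevalence_pct(self) -> float:
        return 100.0 * len(self.model.registry_positives) / self.model.population_size

    def report_frame(self, rounded: bool = True) -> pd.DataFrame:
        return reports_to_frame(self.reports.values(), rounded=rounded)

    def cohort_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.cohort_summaries.values():
            rows.append(
                {
                    "definition": s.definition.label,
                    "n": s.n,
                    "mean_age": None if s.mean_age is None else round_half_up(s.mean_age, 1),
                    "sd_age": None if s.sd_age is None else round_half_up(s.sd_age, 2),
                    "pct_male": None if s.pct_male is None else round_half_up(s.pct_male, 1),
                    "median_claim_days": s.median_claim_days,
                    "iqr_claim_days": (
                        None
                        if s.iqr_claim_days is None
                        else f"({s.iqr_claim_days[0]:g}, {s.iqr_claim_days[1]:g})"
                    ),
                }
            )
        return pd.DataFrame(rows)

    def index_date_frame(self) -> pd.DataFrame:
        rows = [
            (pid, definition.value, idx.isoformat())
            for definition, result in self.classifications.items()
            for pid, idx in sorted(result.index_dates.items())
        ]
        return pd.DataFrame(rows, columns=["patient_id", "definition", "index_date"])

    def summary(self) -> str:
        """Human-readable validation report."""
        model = self.model
        lines = [
            "Chronic dialysis claims-definition validation",
            "=" * 45,
            f"Observation window:  {model.window.start} .. {model.window.end}",
            f"Study population N:  {model.population_size:,}"
            + (
                f" ({len(model.population):,} ids observed)"
                if model.population_size != len(model.population)
                else ""
            ),
            f"Registry positives:  {len(model.registry_positives):,} "
            f"({round_half_up(self.registry_prevalence_pct, 2):.2f}%)",
            "",
            format_report_table(self.reports.values()),
        ]
        cohort = self.cohort_frame()
        if not cohort.empty:
            lines += ["", "Cohort characteristics", "-" * 22, cohort.to_string(index=False)]
        return "\n".join(lines)

    def save(self, directory: PathLike) -> dict[str, "Path"]:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "report_csv": directory / "agreement_report.csv",
            "report_txt": directory / "agreement_report.txt",
            "index_dates": directory / "index_dates.csv",
            "cohort": directory / "cohort_summary.csv",
        }
        self.report_frame().to_csv(paths["report_csv"], index=False)
        paths["report_txt"].write_text(self.summary() + "\n", encoding="utf-8")
        self.index_date_frame().to_csv(paths["index_dates"], index=False)
        self.cohort_frame().to_csv(paths["cohort"], index=False)
        return paths
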