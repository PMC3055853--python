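"""End-to-end validation model, cohort summaries, and report output."""

from __future__ import annotations

from datetime import date, timedelta

import pandas as pd
import pytest

from dialclaims import (
    Claim,
    ClaimsValidation,
    Definition,
    PatientAttributes,
    RegistryRecord,
    round_half_up,
    summarize_cohort,
    to_day_series,
)
from dialclaims.io import Sex

from conftest import series_from_offsets


def _weekly_claims(pid, start, n):
    return [
        Claim(pid, start + timedelta(days=7 * i), "13.99OA") for i in range(n)
    ]


def test_fit_produces_one_report_per_definition(window):
    claims = _weekly_claims("A", date(2008, 1, 7), 30)
    registry = [RegistryRecord("A", date(2007, 5, 1))]
    results = ClaimsValidation(
        claims, registry, window, population={"A", "Z"}
    ).fit()
    assert set(results.reports) == set(Definition)
    for definition, report in results.reports.items():
        assert report.admin_positive_count == results.cohort_summaries[definition].n


def test_registry_positive_requires_start_on_or_before_window_end(window):
    claims = _weekly_claims("A", date(2008, 1, 7), 30)
    registry = [
        RegistryRecord("A", date(2007, 5, 1)),
        RegistryRecord("future", date(2010, 1, 1)),
    ]
    model = ClaimsValidation(claims, registry, window)
    assert model.registry_positives == {"A"}


def test_population_size_pads_true_negative_cell(window):
    claims = _weekly_claims("A", date(2008, 1, 7), 30)
    registry = [RegistryRecord("A", date(2007, 5, 1))]
    results = ClaimsValidation(
        claims, registry, window, population_size=1_000
    ).fit()
    t = results.tables[Definition.ONE_CLAIM]
    assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 999)
    assert results.registry_prevalence_pct == pytest.approx(0.1)


def test_published_d1_membership_pattern_reproduces_kappa(window):
    """Injecting the published 2x2 membership counts with minimal synthetic
    claims at the study N yields the published D1 kappa of 0.793."""
    claims, registry = [], []
    day = date(2008, 6, 2)
    for i in range(1805):  # dual positives: one claim + registry entry
        pid = f"TP{i:05d}"
        claims.append(Claim(pid, day, "13.99B"))
        registry.append(RegistryRecord(pid, date(2008, 1, 10)))
    for i in range(519):  # claims-only
        claims.append(Claim(f"FP{i:05d}", day, "13.99B"))
    for i in range(422):  # registry-only
        registry.append(RegistryRecord(f"FN{i:05d}", date(2008, 1, 10)))
    results = ClaimsValidation(
        claims, registry, window,
        population_size=1_118_097,
        definitions=[Definition.ONE_CLAIM],
    ).fit()
    report = results.reports[Definition.ONE_CLAIM]
    assert (report.table.a, report.table.b, report.table.c) == (1805, 519, 422)
    assert round_half_up(report.kappa, 3) == 0.793
    assert round_half_up(report.sensitivity, 3) == 0.811


def test_empty_claims_give_zero_sensitivity(window):
    registry = [RegistryRecord("A", date(2008, 2, 1))]
    results = ClaimsValidation(
        [], registry, window, definitions=[Definition.ONE_CLAIM]
    ).fit()
    report = results.reports[Definition.ONE_CLAIM]
    assert report.sensitivity == 0.0
    assert report.prevalence_pct == 0.0


def test_empty_population_is_an_error(window):
    with pytest.raises(ValueError, match="empty study population"):
        ClaimsValidation([], [], window)


def test_population_size_below_observed_ids_is_an_error(window):
    claims = _weekly_claims("A", date(2008, 1, 7), 2)
    with pytest.raises(ValueError, match="population_size"):
        ClaimsValidation(claims, [], window, population_size=0)


def test_cohort_summary_statistics(window):
    series = {
        pid: series_from_offsets(range(0, 7 * n, 7), patient_id=pid)
        for pid, n in (("A", 4), ("B", 8), ("C", 14))
    }
    attributes = {
        "A": PatientAttributes("A", 1968, Sex.MALE),   # age 40 in 2008
        "B": PatientAttributes("B", 1958, Sex.FEMALE),  # 50
        "C": PatientAttributes("C", 1948, Sex.MALE),   # 60
    }
    summary = summarize_cohort(
        ["A", "B", "C"], attributes, series, Definition.ONE_CLAIM, 2008
    )
    assert summary.n == 3
    assert summary.mean_age == pytest.approx(50.0)
    assert summary.pct_male == pytest.approx(100 * 2 / 3)
    assert summary.median_claim_days == 8.0


def test_cohort_summary_without_attributes(window):
    series = {"A": series_from_offsets([0, 7], patient_id="A")}
    summary = summarize_cohort(["A"], None, series, Definition.ONE_CLAIM, 2008)
    assert summary.n == 1
    assert summary.mean_age is None and summary.pct_male is None
    assert summary.median_claim_days == 2.0


def test_from_dataframes_constructor(window):
    claims = pd.DataFrame(
        {
            "patient_id": ["A", "A", "B"],
            "service_date": ["2008-01-01", "2008-01-08", "2008-03-01"],
            "procedure_code": ["13.99B", "13.99B", "99.99Z"],
            "setting": ["outpatient", "outpatient", "outpatient"],
        }
    )
    registry = pd.DataFrame({"patient_id": ["A"], "start_date": ["2007-12-01"]})
    model = ClaimsValidation.from_dataframes(
        claims, registry, window, population={"A", "B"}
    )
    assert len(model.claims) == 2  # non-dialysis code dropped
    results = model.fit()
    assert results.reports[Definition.TWO_CLAIMS].sensitivity == 1.0


def test_summary_text_and_save_round_trip(tmp_path, window):
    claims = _weekly_claims("A", date(2008, 1, 7), 30) + [
        Claim("B", date(2008, 5, 1), "13.99B")
    ]
    registry = [RegistryRecord("A", date(2007, 5, 1))]
    results = ClaimsValidation(claims, registry, window).fit()
    text = results.summary()
    assert "Registry positives" in text
    assert "1 outpatient claim" in text
    paths = results.save(tmp_path)
    frame = pd.read_csv(paths["report_csv"])
    assert len(frame) == 4
    index_dates = pd.read_csv(paths["index_dates"])
    # index date is the second claim day for A, first for single-claim B
    d1 = index_dates[index_dates.definition == "d1"].set_index("patient_id")
    assert d1.loc["A", "index_date"] == "2008-01-14"
    assert d1.loc["B", "index_date"] == "2008-05-01"


def test_refit_is_deterministic(tmp_path, window):
    claims = _weekly_claims("A", date(2008, 1, 7), 20)
    registry = [RegistryRecord("A", date(2007, 5, 1))]
    pop = {"A", "Z"}
    first = ClaimsValidation(claims, registry, window, population=pop).fit().summary()
    second = ClaimsValidation(claims, registry, window, population=pop).fit().summary()
    assert first == second
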