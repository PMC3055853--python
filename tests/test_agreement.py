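"""Contingency construction and agreement statistics on 2x2 tables."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from dialclaims import (
    Definition,
    KappaBand,
    TwoByTwo,
    UndefinedStatisticError,
    build_two_by_two,
    kappa,
    kappa_category,
    negative_agreement,
    positive_agreement,
    ppv,
    prevalence_pct,
    report,
    reports_to_frame,
    round_half_up,
    sensitivity,
    specificity,
)

tables = st.tuples(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
).filter(lambda t: sum(t) > 0).map(lambda t: TwoByTwo(*t))


def test_build_two_by_two_hand_enumeration():
    population = {"1", "2", "3", "4", "5", "6"}
    t = build_two_by_two({"1", "2", "3"}, {"2", "3", "4"}, population)
    assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)


def test_build_two_by_two_degenerate_cases():
    pop = {"x", "y"}
    full = build_two_by_two(pop, pop, pop)
    assert (full.a, full.b, full.c, full.d) == (2, 0, 0, 0)
    none = build_two_by_two(set(), {"x"}, pop)
    assert (none.a, none.b) == (0, 0)


def test_build_two_by_two_rejects_ids_outside_population():
    with pytest.raises(ValueError, match="ghost"):
        build_two_by_two({"ghost"}, set(), {"x"})


def test_hand_computed_symmetric_table():
    # p_o = 0.8, p_e = 0.5 -> kappa = 0.6; sensitivity = PPV = 0.8
    t = TwoByTwo(40, 10, 10, 40)
    assert kappa(t) == pytest.approx(0.6)
    assert sensitivity(t) == pytest.approx(0.8)
    assert ppv(t) == pytest.approx(0.8)
    assert positive_agreement(t) == pytest.approx(0.8)


def test_perfect_agreement_statistics_are_one():
    t = TwoByTwo(50, 0, 0, 950)
    assert kappa(t) == pytest.approx(1.0)
    assert sensitivity(t) == ppv(t) == positive_agreement(t) == 1.0
    r = report(Definition.ONE_CLAIM, t)
    assert r.kappa_category is KappaBand.NEAR_PERFECT


def test_undefined_statistics_raise():
    no_registry = TwoByTwo(0, 5, 0, 95)
    with pytest.raises(UndefinedStatisticError):
        sensitivity(no_registry)
    no_claims = TwoByTwo(0, 0, 5, 95)
    with pytest.raises(UndefinedStatisticError):
        ppv(no_claims)
    with pytest.raises(UndefinedStatisticError):
        positive_agreement(TwoByTwo(0, 0, 0, 10))


def test_counts_must_be_non_negative_integers():
    with pytest.raises(ValueError):
        TwoByTwo(-1, 0, 0, 10)
    with pytest.raises(ValueError):
        TwoByTwo(0, 0, 0, 0)


@settings(max_examples=200, derandomize=True)
@given(tables)
def test_kappa_matches_independent_implementation(t):
    """Cross-check the closed-form kappa against scikit-learn on raw labels."""
    registry = [1] * t.a + [0] * t.b + [1] * t.c + [0] * t.d
    admin = [1] * t.a + [1] * t.b + [0] * t.c + [0] * t.d
    if len(set(registry)) == 1 and len(set(admin)) == 1:
        return  # chance agreement 1: kappa undefined
    try:
        ours = kappa(t)
    except UndefinedStatisticError:
        return
    assert ours == pytest.approx(cohen_kappa_score(registry, admin), abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(tables)
def test_kappa_symmetric_under_rater_swap(t):
    swapped = TwoByTwo(t.a, t.c, t.b, t.d)
    try:
        assert kappa(t) == pytest.approx(kappa(swapped), abs=1e-12)
    except UndefinedStatisticError:
        pass


@settings(max_examples=200, derandomize=True)
@given(tables, st.integers(2, 9))
def test_statistics_scale_invariant(t, k):
    scaled = TwoByTwo(t.a * k, t.b * k, t.c * k, t.d * k)
    for stat in (sensitivity, ppv, positive_agreement, kappa):
        try:
            expected = stat(t)
        except UndefinedStatisticError:
            continue
        assert stat(scaled) == pytest.approx(expected, abs=1e-12)


def test_kappa_one_iff_off_diagonal_empty():
    assert kappa(TwoByTwo(3, 0, 0, 7)) == pytest.approx(1.0)
    assert kappa(TwoByTwo(3, 1, 0, 7)) < 1.0
    assert kappa(TwoByTwo(3, 0, 1, 7)) < 1.0


@pytest.mark.parametrize(
    "value, band",
    [
        (0.0, KappaBand.POOR),
        (0.20, KappaBand.POOR),
        (0.21, KappaBand.FAIR),
        (0.40, KappaBand.FAIR),
        (0.41, KappaBand.MODERATE),
        (0.60, KappaBand.MODERATE),
        (0.693, KappaBand.SUBSTANTIAL),
        (0.793, KappaBand.SUBSTANTIAL),
        (0.80, KappaBand.SUBSTANTIAL),
        (0.81, KappaBand.NEAR_PERFECT),
        (1.0, KappaBand.NEAR_PERFECT),
        (-0.2, KappaBand.POOR),
    ],
)
def test_landis_koch_bands(value, band):
    assert kappa_category(value) is band


def test_prevalence_percentage():
    assert prevalence_pct(TwoByTwo(1, 1, 0, 998)) == pytest.approx(0.2)
    assert prevalence_pct(TwoByTwo(0, 0, 5, 995)) == 0.0
    assert prevalence_pct(TwoByTwo(5, 5, 0, 0)) == 100.0


def test_round_half_up_convention():
    assert round_half_up(0.8485, 3) == 0.849
    assert round_half_up(0.0005, 3) == 0.001
    assert round_half_up(0.2078, 2) == 0.21
    assert round_half_up(0.1942, 2) == 0.19


def test_negative_measures_excluded_by_default():
    t = TwoByTwo(40, 10, 10, 940)
    r = report(Definition.ONE_CLAIM, t)
    assert r.specificity is None and r.npv is None and r.negative_agreement is None
    verbose = report(Definition.ONE_CLAIM, t, include_negative=True)
    assert verbose.specificity == pytest.approx(specificity(t))
    assert verbose.npv == pytest.approx(940 / 950)
    assert verbose.negative_agreement == pytest.approx(negative_agreement(t))


def test_report_frame_columns_and_rounding():
    t = TwoByTwo(40, 10, 10, 940)
    frame = reports_to_frame([report(Definition.ONE_CLAIM, t)])
    assert list(frame.columns) == [
        "definition", "admin_positive_n", "prevalence_pct", "a", "b", "c", "d",
        "positive_agreement", "sensitivity", "ppv", "kappa", "kappa_category",
    ]
    row = frame.iloc[0]
    assert row["admin_positive_n"] == 50
    assert row["sensitivity"] == 0.8
    assert np.isclose(row["prevalence_pct"], 5.0)
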