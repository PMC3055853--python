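"""Agreement statistics of a claims definition against the registry.

The analytic framework is the standard 2x2 contingency table against a
reference standard:

====================  ==========  ==========
                      registry +  registry -
====================  ==========  ==========
claims definition +       a           b
claims definition -       c           d
====================  ==========  ==========

with N = a + b + c + d. From it we compute sensitivity a/(a+c), positive
predictive value a/(a+b), the Cicchetti–Feinstein positive agreement
2a/(2a+b+c), and Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e),
    p_o = (a+d)/N,   p_e = [(a+b)(a+c) + (c+d)(b+d)] / N^2.

When the condition is rare (d >> a, b, c), kappa converges to the positive
agreement, which is why validation studies of rare outcomes print near-
identical columns for the two. Specificity, negative agreement, and NPV
are computable but excluded from default reports: with ~10^6 true
negatives they are insensitive to any change in the case definition.

Kappa bands follow the Landis–Koch convention: <= 0.20 poor, (0.20, 0.40]
fair, (0.40, 0.60] moderate, (0.60, 0.80] substantial, > 0.80 near-perfect
agreement.

All statistics are kept at full precision; rounding (half-up, three
decimals for proportions and kappa, two for prevalence percentages)
happens only at serialization.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Set

import pandas as pd

from .definitions import Definition
from .exceptions import UndefinedStatisticError


@dataclass(frozen=True)
class TwoByTwo:
    """Contingency counts of a claims definition vs the registry standard."""

    a: int  # registry+ & claims+
    b: int  # registry- & claims+
    c: int  # registry+ & claims-
    d: int  # registry- & claims-

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("total count N must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


class KappaBand(str, enum.Enum):
    POOR = "poor"
    FAIR = "fair"
    MODERATE = "moderate"
    SUBSTANTIAL = "substantial"
    NEAR_PERFECT = "near_perfect"


def build_two_by_two(
    claims_positives: Set[str], registry_positives: Set[str], population: Set[str]
) -> TwoByTwo:
    """Cross-tabulate claims-definition positives against registry positives."""
    for name, group in (("claims", claims_positives), ("registry", registry_positives)):
        stray = set(group) - set(population)
        if stray:
            shown = ", ".join(sorted(stray)[:10])
            raise ValueError(
                f"{name} positives not contained in population "
                f"({len(stray)} id(s): {shown}{'...' if len(stray) > 10 else ''})"
            )
    a = len(claims_positives & registry_positives)
    b = len(claims_positives - registry_positives)
    c = len(registry_positives - claims_positives)
    d = len(population) - a - b - c
    return TwoByTwo(a, b, c, d)


def sensitivity(t: TwoByTwo) -> float:
    """a/(a+c): probability a registry patient is claims-positive."""
    if t.a + t.c == 0:
        raise UndefinedStatisticError("sensitivity undefined: no registry positives")
    return t.a / (t.a + t.c)


def ppv(t: TwoByTwo) -> float:
    """a/(a+b): probability a claims-positive patient is in the registry."""
    if t.a + t.b == 0:
        raise UndefinedStatisticError("PPV undefined: no claims positives")
    return t.a / (t.a + t.b)


def specificity(t: TwoByTwo) -> float:
    if t.b + t.d == 0:
        raise UndefinedStatisticError("specificity undefined: no registry negatives")
    return t.d / (t.b + t.d)


def npv(t: TwoByTwo) -> float:
    if t.c + t.d == 0:
        raise UndefinedStatisticError("NPV undefined: no claims negatives")
    return t.d / (t.c + t.d)


def positive_agreement(t: TwoByTwo) -> float:
    """Cicchetti–Feinstein positive agreement, 2a/(2a+b+c)."""
    denom = 2 * t.a + t.b + t.c
    if denom == 0:
        raise UndefinedStatisticError("positive agreement undefined: 2a+b+c = 0")
    return 2 * t.a / denom


def negative_agreement(t: TwoByTwo) -> float:
    """2d/(2d+b+c); excluded from default reports like specificity/NPV."""
    denom = 2 * t.d + t.b + t.c
    if denom == 0:
        raise UndefinedStatisticError("negative agreement undefined: 2d+b+c = 0")
    return 2 * t.d / denom


def kappa(t: TwoByTwo) -> float:
    """Cohen's chance-corrected agreement on the 2x2 table."""
    n = t.n
    p_o = (t.a + t.d) / n
    p_e = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / (n * n)
    if p_e == 1.0:
        raise UndefinedStatisticError("kappa undefined: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def kappa_category(k: float) -> KappaBand:
    """Landis–Koch agreement band for a kappa value."""
    if k > 1.0:
        raise ValueError(f"kappa cannot exceed 1, got {k}")
    if k <= 0.20:
        return KappaBand.POOR
    if k <= 0.40:
        return KappaBand.FAIR
    if k <= 0.60:
        return KappaBand.MODERATE
    if k <= 0.80:
        return KappaBand.SUBSTANTIAL
    return KappaBand.NEAR_PERFECT


def prevalence_pct(t: TwoByTwo) -> float:
    """Claims-definition prevalence, 100 * (a+b)/N."""
    return 100.0 * (t.a + t.b) / t.n


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    if x != x:
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AgreementReport:
    """All derived agreement statistics for one case definition."""

    definition: Definition
    table: TwoByTwo
    admin_positive_count: int
    prevalence_pct: float
    sensitivity: float
    ppv: float
    positive_agreement: float
    kappa: float
    kappa_category: KappaBand | None
    specificity: float | None = None
    npv: float | None = None
    negative_agreement: float | None = None

    def __post_init__(self) -> None:
        # NaN marks a statistic whose denominator was empty (non-strict mode)
        for name in ("sensitivity", "ppv", "positive_agreement"):
            v = getattr(self, name)
            if v == v and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v}")
        if not 0.0 <= self.prevalence_pct <= 100.0:
            raise ValueError(f"prevalence_pct out of [0, 100]: {self.prevalence_pct}")
        if self.kappa > 1.0:
            raise ValueError(f"kappa exceeds 1: {self.kappa}")


def report(
    definition: Definition,
    t: TwoByTwo,
    include_negative: bool = False,
    strict: bool = True,
) -> AgreementReport:
    """Assemble the full statistics row for one definition's 2x2 table.

    ``include_negative`` additionally populates specificity, NPV, and
    negative agreement (omitted by default for rare outcomes). With
    ``strict=False``, statistics whose denominator is empty (e.g. PPV on
    a definition with no positives) are reported as NaN instead of
    raising.
    """

    def _stat(fn):
        try:
            return fn(t)
        except UndefinedStatisticError:
            if strict:
                raise
            return float("nan")

    k = _stat(kappa)
    return AgreementReport(
        definition=definition,
        table=t,
        admin_positive_count=t.a + t.b,
        prevalence_pct=prevalence_pct(t),
        sensitivity=_stat(sensitivity),
        ppv=_stat(ppv),
        positive_agreement=_stat(positive_agreement),
        kappa=k,
        kappa_category=kappa_category(k) if k == k else None,
        specificity=_stat(specificity) if include_negative else None,
        npv=_stat(npv) if include_negative else None,
        negative_agreement=_stat(negative_agreement) if include_negative else None,
    )


def reports_to_frame(reports: Iterable[AgreementReport], rounded: bool = True) -> pd.DataFrame:
    """Tabulate reports in the standard validation-table column order."""
    rows = []
    for r in reports:
        row = {
            "definition": r.definition.label,
            "admin_positive_n": r.admin_positive_count,
            "prevalence_pct": r.prevalence_pct,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "positive_agreement": r.positive_agreement,
            "sensitivity": r.sensitivity,
            "ppv": r.ppv,
            "kappa": r.kappa,
            "kappa_category": r.kappa_category.value if r.kappa_category else "",
        }
        if r.specificity is not None:
            row["specificity"] = r.specificity
            row["npv"] = r.npv
            row["negative_agreement"] = r.negative_agreement
        if rounded:
            row["prevalence_pct"] = round_half_up(row["prevalence_pct"], 2)
            for col in (
                "positive_agreement",
                "sensitivity",
                "ppv",
                "kappa",
                "specificity",
                "npv",
                "negative_agreement",
            ):
                if col in row:
                    row[col] = round_half_up(row[col], 3)
        rows.append(row)
    return pd.DataFrame(rows)


def format_report_table(reports: Iterable[AgreementReport]) -> str:
    """Aligned text rendering of the validation table."""
    return reports_to_frame(reports).to_string(index=False)
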