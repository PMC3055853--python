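"""Synthetic claims, registry, and ground-truth generator.

Emulates the data-generating process behind outpatient dialysis billing:

* **Chronic (registry) patients** — a configurable fraction are prevalent
  (already on dialysis at window start, registered since 1999) and the
  rest start during the window. Hemodialysis patients bill a per-week
  management code; peritoneal-dialysis patients bill a monthly assessment
  code (a per-session mode is available). Each due claim is actually
  billed with probability ``claim_capture_prob`` — missed billings,
  billing errors, and shadow billing by salaried physicians all present
  as dropped claims. An exponential early-death hazard truncates the
  billing stream: no claims are emitted on or after the death date.
* **Temporary (AKI) dialysis patients** — a small fraction of the
  non-registry population has an acute-kidney-injury dialysis episode: a
  burst of unstable-hemodialysis claims at a short interval, with episode
  duration truncated below 90 days so temporary dialysis can never span
  the 90-day rules. Episodes of duration 1 model stray single-claim
  billing errors.
* **Unexposed patients** — no dialysis claims at all.

Output is fully reproducible for a fixed seed; ``write_fixture`` emits
byte-identical claims/registry/truth CSVs in the formats the readers
consume.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .exceptions import ScenarioError
from .io import (
    Claim,
    ObservationWindow,
    PathLike,
    RegistryRecord,
    Setting,
    WINDOW_2008,
    write_claims,
    write_registry,
)

#: Registration horizon for prevalent patients (registry opened 1999).
REGISTRY_EPOCH = date(1999, 1, 1)

HD_WEEKLY_CODE = "13.99OA"
HD_SESSION_CODE = "13.99B"
PD_MONTHLY_CODE = "13.99D"
AKI_CODE = "13.99A"


class TruthLabel(str, enum.Enum):
    CHRONIC = "chronic_dialysis"
    TEMPORARY = "temporary_dialysis"
    UNEXPOSED = "unexposed"


@dataclass(frozen=True)
class GroundTruth:
    patient_id: str
    label: TruthLabel
    dialysis_start: date | None = None
    death_date: date | None = None


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one synthetic population.

    Defaults reflect the study setting: registry prevalence 0.2% of the
    creatinine-tested adult population, weekly hemodialysis management
    billing, monthly peritoneal-dialysis billing, modest billing
    under-capture, a rare short temporary-dialysis (AKI) episode rate of
    the same order as the observed false-positive excess, and a per-day
    early-death hazard of ~0.1% (roughly 30% annual dialysis mortality).
    """

    n_population: int = 50_000
    window: ObservationWindow = field(default_factory=lambda: WINDOW_2008)
    registry_prevalence: float = 0.002
    prevalent_fraction: float = 0.75
    hd_fraction: float = 0.8
    hd_claim_period_days: int = 7
    pd_claim_period_days: int = 30
    per_session_billing: bool = False
    session_interval_days: int = 3
    claim_capture_prob: float = 0.95
    aki_rate: float = 0.0005
    aki_mean_duration_days: float = 30.0
    aki_duration_shape: float = 1.5
    aki_max_duration_days: int = 89
    aki_claim_interval_days: int = 3
    early_death_hazard: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.n_population < 1:
            raise ScenarioError("n_population", "must be >= 1")
        for name in (
            "registry_prevalence",
            "prevalent_fraction",
            "hd_fraction",
            "claim_capture_prob",
            "aki_rate",
            "early_death_hazard",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(name, f"must be a probability in [0, 1], got {v}")
        for name in (
            "hd_claim_period_days",
            "pd_claim_period_days",
            "session_interval_days",
            "aki_claim_interval_days",
        ):
            if getattr(self, name) < 1:
                raise ScenarioError(name, "must be >= 1 day")
        if self.aki_mean_duration_days <= 0:
            raise ScenarioError("aki_mean_duration_days", "must be positive")
        if self.aki_duration_shape <= 0:
            raise ScenarioError("aki_duration_shape", "must be positive")
        if self.aki_max_duration_days < 1:
            raise ScenarioError("aki_max_duration_days", "must be >= 1 day")


@dataclass(frozen=True)
class SimOutput:
    """Everything one simulation run produced."""

    scenario: SimScenario
    claims: tuple[Claim, ...]
    registry: tuple[RegistryRecord, ...]
    truth: tuple[GroundTruth, ...]


def _emit_stream(
    rng: np.random.Generator,
    first: date,
    last: date,
    period: int,
    capture: float,
) -> list[date]:
    """Due claim days every ``period`` days in [first, last], thinned by capture."""
    days: list[date] = []
    current = first
    while current <= last:
        if capture >= 1.0 or rng.random() < capture:
            days.append(current)
        current = current + timedelta(days=period)
    return days


def simulate(scenario: SimScenario) -> SimOutput:
    """Generate one synthetic population of claims, registry, and truth."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    window = scenario.window
    n = scenario.n_population
    width = max(6, len(str(n)))
    ids = [f"P{i:0{width}d}" for i in range(n)]

    u = rng.random(n)
    is_registry = u < scenario.registry_prevalence
    # AKI drawn only among non-registry patients, on an independent stream
    is_aki = (~is_registry) & (rng.random(n) < scenario.aki_rate)

    claims: list[Claim] = []
    registry: list[RegistryRecord] = []
    truth: list[GroundTruth] = []

    for i, pid in enumerate(ids):
        if is_registry[i]:
            prevalent = rng.random() < scenario.prevalent_fraction
            if prevalent:
                lead = int(rng.integers(1, (window.start - REGISTRY_EPOCH).days + 1))
                start = window.start - timedelta(days=lead)
            else:
                start = window.start + timedelta(
                    days=int(rng.integers(0, window.n_days))
                )
            hd = rng.random() < scenario.hd_fraction
            if hd:
                if scenario.per_session_billing:
                    period, code = scenario.session_interval_days, HD_SESSION_CODE
                else:
                    period, code = scenario.hd_claim_period_days, HD_WEEKLY_CODE
            else:
                period, code = scenario.pd_claim_period_days, PD_MONTHLY_CODE

            # Prevalent patients are alive and on dialysis at window start by
            # definition; their survival clock runs from there (memoryless).
            death: date | None = None
            if scenario.early_death_hazard > 0:
                death = max(start, window.start) + timedelta(
                    days=int(rng.geometric(scenario.early_death_hazard))
                )
            first = max(start, window.start)
            last = window.end
            if death is not None:
                last = min(last, death - timedelta(days=1))
            days = (
                _emit_stream(rng, first, last, period, scenario.claim_capture_prob)
                if first <= last
                else []
            )
            claims.extend(
                Claim(pid, day, code, Setting.OUTPATIENT) for day in days
            )
            registry.append(RegistryRecord(pid, start))
            truth.append(GroundTruth(pid, TruthLabel.CHRONIC, start, death))
        elif is_aki[i]:
            episode_start = window.start + timedelta(
                days=int(rng.integers(0, window.n_days))
            )
            raw = rng.gamma(
                scenario.aki_duration_shape,
                scenario.aki_mean_duration_days / scenario.aki_duration_shape,
            )
            duration = int(np.clip(round(raw), 1, scenario.aki_max_duration_days))
            episode_end = episode_start + timedelta(days=duration - 1)
            days = _emit_stream(
                rng,
                episode_start,
                min(episode_end, window.end),
                scenario.aki_claim_interval_days,
                scenario.claim_capture_prob,
            )
            claims.extend(Claim(pid, day, AKI_CODE, Setting.OUTPATIENT) for day in days)
            truth.append(GroundTruth(pid, TruthLabel.TEMPORARY, episode_start, None))
        else:
            truth.append(GroundTruth(pid, TruthLabel.UNEXPOSED))

    return SimOutput(
        scenario=scenario,
        claims=tuple(sorted(claims)),
        registry=tuple(sorted(registry)),
        truth=tuple(truth),
    )


def write_truth(truth: Iterable[GroundTruth], path: PathLike) -> None:
    import pandas as pd

    frame = pd.DataFrame(
        [
            (
                t.patient_id,
                t.label.value,
                t.dialysis_start.isoformat() if t.dialysis_start else "",
                t.death_date.isoformat() if t.death_date else "",
            )
            for t in truth
        ],
        columns=["patient_id", "label", "dialysis_start", "death_date"],
    )
    frame.to_csv(path, index=False)


def scenario_to_dict(scenario: SimScenario) -> dict:
    return {
        "n_population": scenario.n_population,
        "window_start": scenario.window.start.isoformat(),
        "window_end": scenario.window.end.isoformat(),
        "registry_prevalence": scenario.registry_prevalence,
        "prevalent_fraction": scenario.prevalent_fraction,
        "hd_fraction": scenario.hd_fraction,
        "hd_claim_period_days": scenario.hd_claim_period_days,
        "pd_claim_period_days": scenario.pd_claim_period_days,
        "per_session_billing": scenario.per_session_billing,
        "session_interval_days": scenario.session_interval_days,
        "claim_capture_prob": scenario.claim_capture_prob,
        "aki_rate": scenario.aki_rate,
        "aki_mean_duration_days": scenario.aki_mean_duration_days,
        "aki_duration_shape": scenario.aki_duration_shape,
        "aki_max_duration_days": scenario.aki_max_duration_days,
        "aki_claim_interval_days": scenario.aki_claim_interval_days,
        "early_death_hazard": scenario.early_death_hazard,
        "seed": scenario.seed,
    }


def scenario_from_dict(data: dict) -> SimScenario:
    data = dict(data)
    window = WINDOW_2008
    if "window_start" in data or "window_end" in data:
        window = ObservationWindow(
            date.fromisoformat(data.pop("window_start")),
            date.fromisoformat(data.pop("window_end")),
        )
    known = set(SimScenario.__dataclass_fields__) - {"window"}
    unknown = set(data) - known
    if unknown:
        raise ScenarioError(sorted(unknown)[0], "unknown scenario key")
    return SimScenario(window=window, **data)


def load_scenario(path: PathLike) -> SimScenario:
    """Read a flat key-value scenario file (YAML mapping of scalar keys)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ScenarioError("<file>", "scenario file must be a flat key: value mapping")
    return scenario_from_dict(data)


def write_fixture(output: SimOutput, directory: PathLike) -> dict[str, Path]:
    """Write claims.csv, registry.csv, truth.csv, and a scenario echo.

    Files round-trip losslessly through the package readers, and are
    byte-identical across runs with the same seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "claims": directory / "claims.csv",
        "registry": directory / "registry.csv",
        "truth": directory / "truth.csv",
        "scenario": directory / "scenario.yaml",
    }
    write_claims(output.claims, paths["claims"])
    write_registry(output.registry, paths["registry"])
    write_truth(output.truth, paths["truth"])
    with open(paths["scenario"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(scenario_to_dict(output.scenario), fh, sort_keys=True)
    return paths


def with_seed(scenario: SimScenario, seed: int) -> SimScenario:
    """Convenience: the same scenario with a different seed."""
    return replace(scenario, seed=seed)
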