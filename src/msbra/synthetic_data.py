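"""Packaged input tables and synthetic generators for every pipeline stage.

Two generative models mirror the assumptions of the estimation stages:

* trial arms drawn from the hierarchical beta-binomial model (a study-level
  success probability per arm, binomial counts given it), used to validate
  parameter recovery of the meta-analytic fitter;
* spontaneous case-report collections with a known true incidence, in the
  regime where the reporting-ratio upper limit is a valid bound: every true
  case is reported with the drug suspected and onset within the filter
  window, while padding reports dilute only the denominator.

The in-study input tables (adverse-effect inclusion, effectiveness arms,
non-serious-risk arms, serious-risk upper limits) ship as tab-separated
fixtures with a checksum manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .effectiveness_meta import StudyArm
from .serious_risks import CaseReport, DrugRole
from .tree_model import AdverseEffectSpec, SeriousOutcome

__all__ = [
    "ArmSimulationSpec",
    "ReportSimulationSpec",
    "StudyFixtures",
    "simulate_arms",
    "simulate_reports",
    "study_fixtures",
]

#: Placebo arms act as the no-treatment proxy in fixture tables.
PLACEBO = "PLACEBO"


@dataclass(frozen=True)
class ArmSimulationSpec:
    """True hyperparameters and arm sizes for simulated trial arms."""

    mu: float
    concentration: float
    sizes: tuple[int, ...]
    seed: int | None = None
    alternative: str = "SIMULATED"

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError("mu must lie in (0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not self.sizes or any(n < 1 for n in self.sizes):
            raise ValueError("arm sizes must be positive")


def simulate_arms(spec: ArmSimulationSpec) -> list[StudyArm]:
    """Beta-binomial arms: p_i ~ Beta(mu M, (1-mu) M), x_i ~ Bin(n_i, p_i)."""
    rng = np.random.default_rng(spec.seed)
    a = spec.mu * spec.concentration
    b = (1.0 - spec.mu) * spec.concentration
    arms = []
    for i, n in enumerate(spec.sizes):
        p = rng.beta(a, b)
        x = int(rng.binomial(n, p))
        arms.append(
            StudyArm(study=f"sim-{i}", alternative=spec.alternative, successes=x, size=n)
        )
    return arms


@dataclass(frozen=True)
class ReportSimulationSpec:
    """Reporting process with known true incidence.

    ``incidence`` maps (effect, outcome) to the per-person probability of a
    true case over the exposure window.  Cases are reported with probability
    ``reporting_probability`` as suspected-role reports with onset within
    the filter window.  ``n_noncase`` padding reports are appended; by
    default they are concomitant-role with another drug implicated, so they
    enlarge only the denominator of the reporting ratio.
    """

    population: int
    incidence: Mapping[tuple[str, SeriousOutcome], float]
    reporting_probability: float = 1.0
    n_noncase: int = 0
    noncase_role: DrugRole = DrugRole.CONCOMITANT
    noncase_other_drug: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ValueError("population must be positive")
        if not 0.0 <= self.reporting_probability <= 1.0:
            raise ValueError("reporting probability must lie in [0, 1]")
        if any(not 0.0 <= v <= 1.0 for v in self.incidence.values()):
            raise ValueError("incidences must lie in [0, 1]")


def simulate_reports(spec: ReportSimulationSpec) -> list[CaseReport]:
    """Simulate one spontaneous-report collection."""
    rng = np.random.default_rng(spec.seed)
    reports: list[CaseReport] = []
    for (effect, outcome), p in spec.incidence.items():
        n_cases = int(rng.binomial(spec.population, p))
        n_reported = (
            n_cases
            if spec.reporting_probability == 1.0
            else int(rng.binomial(n_cases, spec.reporting_probability))
        )
        for i in range(n_reported):
            reports.append(
                CaseReport(
                    id=f"case-{effect}-{outcome.value}-{i}",
                    drug_role=DrugRole.SUSPECTED,
                    reactions=((effect, outcome),),
                    other_drug_implicated=False,
                    time_to_onset_days=int(rng.integers(0, 181)),
                )
            )
    for i in range(spec.n_noncase):
        reports.append(
            CaseReport(
                id=f"noncase-{i}",
                drug_role=spec.noncase_role,
                reactions=(("unrelated reaction", None),),
                other_drug_implicated=spec.noncase_other_drug,
                time_to_onset_days=int(rng.integers(0, 181)),
            )
        )
    return reports


@dataclass
class StudyFixtures:
    """Typed bundle of the packaged input tables."""

    effects: tuple[AdverseEffectSpec, ...]
    effectiveness_arms: dict[str, list[StudyArm]]  # HIGH_DOSE / LOW_DOSE / PLACEBO
    nonserious_arms: dict[str, list[StudyArm]]  # HIGH_DOSE / PLACEBO
    risk_limit_table: pd.DataFrame
    checksums: dict[str, str] = field(default_factory=dict)

    @property
    def n_combinations(self) -> int:
        return sum(len(e.included_outcomes) for e in self.effects)


_FIXTURE_FILES = (
    "adverse_effects.tsv",
    "effectiveness_arms.tsv",
    "nonserious_arms.tsv",
    "risk_limits.tsv",
)


def _data_text(name: str) -> str:
    return resources.files("msbra.data").joinpath(name).read_text(encoding="utf-8")


def _verify_checksums() -> dict[str, str]:
    manifest = json.loads(_data_text("manifest.json"))
    seen = {}
    for name in _FIXTURE_FILES:
        digest = hashlib.sha256(_data_text(name).encode("utf-8")).hexdigest()
        if manifest.get(name) != digest:
            raise ValueError(
                f"fixture {name} does not match its manifest checksum; "
                "the packaged data appear corrupted"
            )
        seen[name] = digest
    return seen


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("msbra.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def _arms_from_table(df: pd.DataFrame, day_column: str) -> dict[str, list[StudyArm]]:
    arms: dict[str, list[StudyArm]] = {}
    for row in df.itertuples(index=False):
        arm = StudyArm(
            study=row.study,
            alternative=row.alternative,
            successes=float(row.successes),
            size=int(row.size),
            route=row.route,
            duration_days=row.duration_days,
            assessment_day=getattr(row, day_column),
        )
        arms.setdefault(row.alternative, []).append(arm)
    return arms


def study_fixtures() -> StudyFixtures:
    """Load, checksum-verify and type the packaged input tables."""
    checksums = _verify_checksums()

    t1 = _read_table("adverse_effects.tsv")
    effects = []
    for row in t1.itertuples(index=False):
        included = tuple(
            outcome
            for outcome, flag in (
                (SeriousOutcome.DEATH, row.death),
                (SeriousOutcome.PERSISTENT, row.persistent),
                (SeriousOutcome.LIFE_THREATENING, row.life_threatening),
            )
            if flag.strip().lower() == "yes"
        )
        effects.append(AdverseEffectSpec(name=row.effect, included_outcomes=included))

    t2 = _read_table("effectiveness_arms.tsv")
    t3 = _read_table("nonserious_arms.tsv")
    t4 = _read_table("risk_limits.tsv")
    t4 = t4.assign(low_pct=t4.low_pct.astype(float), high_pct=t4.high_pct.astype(float))

    return StudyFixtures(
        effects=tuple(effects),
        effectiveness_arms=_arms_from_table(t2, "assessment_day"),
        nonserious_arms=_arms_from_table(t3, "followup_days"),
        risk_limit_table=t4,
        checksums=checksums,
    )
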