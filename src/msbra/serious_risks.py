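"""Serious-risk bounds from spontaneous case reports, and risk sampling.

Clinical trials of methylprednisolone in MS relapses are far too small to
estimate the risks of rare serious adverse effects.  Instead, for each
included effect-outcome combination an upper limit ``L`` on the true
population risk is computed as a reporting ratio within a collection of
individual case reports: qualifying reports carrying the combination,
divided by all reports listing the drug at the relevant dose.  A report
qualifies for the numerator if the drug is listed as suspected or
interacting, or as concomitant with no other drug implicated, and the time
from drug initiation to reaction onset is at most 180 days (the onset filter
is waived for osteonecrosis, which is hard to date diagnostically).

The true risk is then modelled over the interval [0, L] with either a
uniform distribution or an exponential with rate ``k / L`` truncated to
[0, L] (k = 5, 50, 500 spans increasingly optimistic beliefs).  The no
treatment alternative carries a background share ``pi`` of the average
active-treatment risk.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .tree_model import OUTCOME_RANK, Alternative, SeriousOutcome

__all__ = [
    "DrugRole",
    "CaseReport",
    "RiskLimit",
    "RiskFamily",
    "RiskDistributionSpec",
    "classify_report",
    "select_combinations",
    "compute_upper_limit",
    "sample_risk",
    "truncated_exp_mean",
    "background_risk",
    "outcome_fraction",
    "effective_limits",
]

#: Longest accepted time from drug initiation to reaction onset (days).
MAX_ONSET_DAYS = 180


class DrugRole(str, enum.Enum):
    """Role the drug holds on a spontaneous case report."""

    SUSPECTED = "SUSPECTED"
    INTERACTING = "INTERACTING"
    CONCOMITANT = "CONCOMITANT"


@dataclass(frozen=True)
class CaseReport:
    """One spontaneous report listing the drug.

    ``reactions`` pairs an adverse-effect name with the outcome evidence on
    the report (``None`` when the reaction carries no serious outcome).
    ``other_drug_implicated`` matters only for the CONCOMITANT role.
    """

    id: str
    drug_role: DrugRole
    reactions: tuple[tuple[str, SeriousOutcome | None], ...]
    other_drug_implicated: bool = False
    time_to_onset_days: int | None = None

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValueError(f"report {self.id}: reactions must be non-empty")


@dataclass(frozen=True)
class RiskLimit:
    """Upper bound on the population risk of one effect-outcome-alternative."""

    effect: str
    outcome: SeriousOutcome
    alternative: Alternative | None
    limit: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.limit <= 1.0):
            raise ValueError("risk limit must lie in [0, 1]")


class RiskFamily(str, enum.Enum):
    UNIFORM = "UNIFORM"
    TRUNC_EXP = "TRUNC_EXP"


@dataclass(frozen=True)
class RiskDistributionSpec:
    """Distribution over a risk interval [0, L].

    ``rate_multiplier`` k sets the truncated-exponential rate to ``k / L``;
    the study scenarios use k in {5, 50, 500}.
    """

    family: RiskFamily = RiskFamily.UNIFORM
    rate_multiplier: float = 5.0

    def __post_init__(self) -> None:
        if self.family is RiskFamily.TRUNC_EXP and self.rate_multiplier <= 0:
            raise ValueError("rate multiplier must be positive")

    def name(self) -> str:
        if self.family is RiskFamily.UNIFORM:
            return "UNIFORM"
        return f"TRUNC_EXP(k={self.rate_multiplier:g})"


def classify_report(r: CaseReport) -> dict[str, SeriousOutcome]:
    """Hierarchical outcome classification of one report, per effect.

    For each distinct adverse effect on the report, only the highest-priority
    serious outcome present counts (death > persistent disability >
    life-threatening).  Different effects on the same report are classified
    separately.  Reactions without serious-outcome evidence are ignored.
    """
    best: dict[str, SeriousOutcome] = {}
    for effect, evidence in r.reactions:
        if evidence is None:
            continue
        current = best.get(effect)
        if current is None or OUTCOME_RANK[evidence] < OUTCOME_RANK[current]:
            best[effect] = evidence
    return best


def select_combinations(
    counts: Mapping[tuple[str, SeriousOutcome], tuple[float, float]],
    min_total: int = 3,
) -> set[tuple[str, SeriousOutcome]]:
    """Keep effect-outcome combinations reported at least ``min_total`` times
    across the two dose groups together."""
    included = set()
    for combo, (n_low, n_high) in counts.items():
        if n_low < 0 or n_high < 0:
            raise ValueError(f"negative count for {combo}")
        if n_low + n_high >= min_total:
            included.add(combo)
    return included


def _qualifies_numerator(r: CaseReport, exempt_onset_filter: bool) -> bool:
    if r.drug_role is DrugRole.CONCOMITANT and r.other_drug_implicated:
        return False
    if not exempt_onset_filter:
        # Missing onset excludes the report from the numerator (conservative
        # only for the denominator; switchable by the onset exemption).
        if r.time_to_onset_days is None or r.time_to_onset_days > MAX_ONSET_DAYS:
            return False
    return True


def compute_upper_limit(
    reports: Sequence[CaseReport],
    effect: str,
    outcome: SeriousOutcome,
    exempt_onset_filter: bool = False,
    alternative: Alternative | None = None,
) -> RiskLimit:
    """Reporting-ratio upper limit for one effect-outcome combination.

    Numerator: reports carrying the combination after hierarchical
    classification that pass the role and onset filters.  Denominator: every
    report in the collection.
    """
    if not reports:
        raise ValueError("cannot compute a reporting ratio on an empty collection")
    numerator = 0
    for r in reports:
        if classify_report(r).get(effect) != outcome:
            continue
        if _qualifies_numerator(r, exempt_onset_filter):
            numerator += 1
    return RiskLimit(effect, outcome, alternative, numerator / len(reports))


def sample_risk(
    L: float,
    spec: RiskDistributionSpec,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` risk values on [0, L] from the given interval distribution.

    Truncated-exponential draws use the inverse CDF,
    ``x = -(1/lam) * ln(1 - U * (1 - exp(-lam L)))`` with ``lam = k / L``.
    A zero limit degenerates to the all-zero vector.
    """
    if L < 0:
        raise ValueError("upper limit must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if L == 0.0:
        rng.random(n)  # keep the stream advancing uniformly across limits
        return np.zeros(n)
    u = rng.random(n)
    if spec.family is RiskFamily.UNIFORM:
        return u * L
    lam = spec.rate_multiplier / L
    return -np.log1p(-u * (-np.expm1(-lam * L))) / lam


def truncated_exp_mean(L: float, k: float) -> float:
    """Mean of an Exponential(k/L) truncated to [0, L].

    Closed form ``1/lam - L * exp(-lam L) / (1 - exp(-lam L))`` with
    ``lam = k / L``; approaches L/2 as k -> 0 (the uniform limit) and 1/lam
    as k grows.
    """
    if L <= 0 or k <= 0:
        raise ValueError("L and k must be positive")
    lam = k / L
    return 1.0 / lam - L * math.exp(-lam * L) / -math.expm1(-lam * L)


def background_risk(q_low, q_high, proportion: float):
    """Serious risk assigned to the no treatment alternative.

    The average of the sampled low- and high-dose values, multiplied by the
    background proportion ``pi`` in [0, 0.5].
    """
    if not (0.0 <= proportion <= 0.5):
        raise ValueError("background proportion must lie in [0, 0.5]")
    return proportion * (np.asarray(q_low) + np.asarray(q_high)) / 2.0


def outcome_fraction(q: Sequence[float] | np.ndarray) -> np.ndarray:
    """Conditional outcome distribution within one adverse effect.

    Given unconditional per-outcome risks, the conditional probability of a
    particular outcome is its fraction of the effect's total risk.
    """
    arr = np.asarray(q, dtype=float)
    if np.any(arr < 0):
        raise ValueError("risks must be non-negative")
    total = arr.sum()
    if total == 0.0:
        raise ValueError("conditional outcome distribution undefined for all-zero risks")
    return arr / total


def effective_limits(
    table,
) -> dict[tuple[str, SeriousOutcome], dict[Alternative, float]]:
    """Per-combination limits (as proportions) for both active alternatives.

    ``table`` is the packaged risk-limit table (a DataFrame with columns
    effect, outcome, low_pct, high_pct, onset_exempt, high_from_low).  Where
    a printed high-dose limit of 0.00 is flagged as not a genuine upper
    bound, the corresponding low-dose limit is substituted.
    """
    limits: dict[tuple[str, SeriousOutcome], dict[Alternative, float]] = {}
    for row in table.itertuples(index=False):
        outcome = SeriousOutcome(row.outcome)
        low = float(row.low_pct) / 100.0
        high = float(row.high_pct) / 100.0
        if str(row.high_from_low).lower() in ("yes", "true", "1"):
            high = low
        limits[(row.effect, outcome)] = {
            Alternative.LOW_DOSE: low,
            Alternative.HIGH_DOSE: high,
        }
    return limits
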