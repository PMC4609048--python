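"""Decision-tree model for the three-way treatment comparison.

The assessment compares three alternatives for an acute multiple sclerosis
relapse: high-dose methylprednisolone (>= 2000 mg cumulative over at most 31
days), low-dose methylprednisolone (< 1000 mg over the same window) and no
treatment.  Every alternative is followed by an identical sub-tree: the
relapse is either *reduced* (improvement of at least one EDSS point within
14-28 days of treatment start) or *standard*; conditional on that, the
patient experiences exactly one of the included serious adverse
effect-outcome combinations, or else at least one non-serious adverse
event, or no adverse event at all.  Serious effects are treated as mutually
exclusive because they are individually rare.

Each leaf of the sub-tree is one clinical outcome.  With ``k`` included
serious effect-outcome combinations the tree has ``2 * (k + 2)`` outcomes;
the full specification of 26 combinations yields 56.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Alternative",
    "BenefitState",
    "SeriousOutcome",
    "AdverseEffectSpec",
    "ClinicalOutcome",
    "DecisionTree",
    "IterationProbabilities",
    "build_tree",
    "outcome_probabilities",
    "expected_utility",
]


class Alternative(str, enum.Enum):
    """The three treatment alternatives under comparison."""

    HIGH_DOSE = "HIGH_DOSE"
    LOW_DOSE = "LOW_DOSE"
    NO_TREATMENT = "NO_TREATMENT"


#: Dose definitions attached to each alternative (cumulative methylprednisolone
#: over at most 31 days); informational metadata only.
DOSE_DEFINITIONS: Mapping[Alternative, str] = {
    Alternative.HIGH_DOSE: ">=2000 mg cumulative over <=31 days",
    Alternative.LOW_DOSE: "<1000 mg cumulative over <=31 days",
    Alternative.NO_TREATMENT: "no methylprednisolone",
}

#: Canonical ordering used everywhere arrays are indexed by alternative.
ALTERNATIVES: tuple[Alternative, ...] = (
    Alternative.HIGH_DOSE,
    Alternative.LOW_DOSE,
    Alternative.NO_TREATMENT,
)


class BenefitState(str, enum.Enum):
    REDUCED = "REDUCED"
    STANDARD = "STANDARD"


class SeriousOutcome(str, enum.Enum):
    """Serious outcome of an adverse effect, in hierarchy order.

    Within a single case report an adverse effect is classified by the
    highest-ranking outcome present: death outranks persistent disability,
    which outranks a life-threatening but non-lethal reaction.
    """

    DEATH = "DEATH"
    PERSISTENT = "PERSISTENT"
    LIFE_THREATENING = "LIFE_THREATENING"


#: Hierarchy rank, lower is more severe / higher priority.
OUTCOME_RANK: Mapping[SeriousOutcome, int] = {
    SeriousOutcome.DEATH: 0,
    SeriousOutcome.PERSISTENT: 1,
    SeriousOutcome.LIFE_THREATENING: 2,
}


@dataclass(frozen=True)
class AdverseEffectSpec:
    """A serious adverse effect and the outcomes included for it."""

    name: str
    included_outcomes: tuple[SeriousOutcome, ...]

    def __post_init__(self) -> None:
        if not self.included_outcomes:
            raise ValueError(f"effect {self.name!r} has no included outcomes")
        if len(set(self.included_outcomes)) != len(self.included_outcomes):
            raise ValueError(f"effect {self.name!r} repeats an outcome")


# Sentinels for the two non-serious branches of the tree.
NO_AE = "NO_AE"
NON_SERIOUS = "NON_SERIOUS"


@dataclass(frozen=True)
class ClinicalOutcome:
    """One leaf of the shared sub-tree.

    ``effect``/``outcome`` are set for serious branches and ``None`` for the
    NO_AE / NON_SERIOUS branches, whose identity is carried by ``branch``.
    """

    benefit: BenefitState
    branch: str  # effect name, or NO_AE / NON_SERIOUS
    outcome: SeriousOutcome | None = None

    @property
    def is_serious(self) -> bool:
        return self.branch not in (NO_AE, NON_SERIOUS)

    def label(self) -> str:
        if self.is_serious:
            return f"{self.benefit.value}|{self.branch}|{self.outcome.value}"
        return f"{self.benefit.value}|{self.branch}"


@dataclass(frozen=True)
class DecisionTree:
    """Alternatives plus the ordered clinical-outcome list they share."""

    effects: tuple[AdverseEffectSpec, ...]
    outcomes: tuple[ClinicalOutcome, ...]
    combinations: tuple[tuple[str, SeriousOutcome], ...] = field(repr=False)

    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)

    @property
    def n_combinations(self) -> int:
        return len(self.combinations)


def build_tree(effects: Iterable[AdverseEffectSpec]) -> DecisionTree:
    """Build the shared decision tree from a set of adverse-effect specs.

    Outcome order is deterministic: for each benefit state (REDUCED first),
    the serious combinations (effects alphabetically, outcomes in hierarchy
    order), then the NON_SERIOUS branch, then NO_AE.
    """
    effects = tuple(sorted(effects, key=lambda s: s.name.lower()))
    names = [s.name for s in effects]
    if len(set(names)) != len(names):
        raise ValueError("duplicate adverse-effect names")

    combinations: list[tuple[str, SeriousOutcome]] = []
    for spec in effects:
        for outcome in sorted(spec.included_outcomes, key=OUTCOME_RANK.__getitem__):
            combinations.append((spec.name, outcome))

    outcomes: list[ClinicalOutcome] = []
    for benefit in (BenefitState.REDUCED, BenefitState.STANDARD):
        for name, outcome in combinations:
            outcomes.append(ClinicalOutcome(benefit, name, outcome))
        outcomes.append(ClinicalOutcome(benefit, NON_SERIOUS))
        outcomes.append(ClinicalOutcome(benefit, NO_AE))

    return DecisionTree(effects, tuple(outcomes), tuple(combinations))


@dataclass(frozen=True)
class IterationProbabilities:
    """One joint draw of all probability variables for all alternatives.

    ``effectiveness`` and ``nonserious`` map alternative -> probability;
    ``serious`` maps alternative -> {(effect, outcome) -> probability}.
    The serious risks are unconditional per-combination probabilities; the
    non-serious risk applies conditionally on no serious effect.
    """

    effectiveness: Mapping[Alternative, float]
    nonserious: Mapping[Alternative, float]
    serious: Mapping[Alternative, Mapping[tuple[str, SeriousOutcome], float]]

    def validate(self) -> None:
        for alt in self.effectiveness:
            e = self.effectiveness[alt]
            r = self.nonserious[alt]
            if not (0.0 <= e <= 1.0 and 0.0 <= r <= 1.0):
                raise ValueError(f"probabilities out of [0, 1] for {alt}")
            q = self.serious[alt]
            if any(v < 0.0 or v > 1.0 for v in q.values()):
                raise ValueError(f"serious risks out of [0, 1] for {alt}")
            if sum(q.values()) >= 1.0:
                raise ValueError(f"serious risks sum to >= 1 for {alt}")


def outcome_probabilities(
    p: IterationProbabilities, alt: Alternative, tree: DecisionTree
) -> np.ndarray:
    """Per-outcome probabilities for one alternative, aligned with the tree.

    Factorisation down the tree: with effectiveness ``e``, serious risks
    ``q_j`` and non-serious risk ``r``,

    * ``P(REDUCED, combination j) = e * q_j``
    * ``P(REDUCED, NON_SERIOUS)  = e * (1 - sum q) * r``
    * ``P(REDUCED, NO_AE)        = e * (1 - sum q) * (1 - r)``

    and analogously with ``1 - e`` for STANDARD.  The result sums to one.
    """
    e = float(p.effectiveness[alt])
    r = float(p.nonserious[alt])
    q = p.serious[alt]
    missing = [c for c in tree.combinations if c not in q]
    if missing:
        raise ValueError(f"serious risks missing for combinations {missing[:3]}")
    q_vec = np.array([q[c] for c in tree.combinations], dtype=float)
    sum_q = q_vec.sum()
    if sum_q >= 1.0:
        raise ValueError("serious risks sum to >= 1")

    half = np.concatenate([q_vec, [(1.0 - sum_q) * r, (1.0 - sum_q) * (1.0 - r)]])
    return np.concatenate([e * half, (1.0 - e) * half])


def expected_utility(
    probabilities: Sequence[float] | np.ndarray,
    utilities: Sequence[float] | np.ndarray,
) -> float:
    """Probability-weighted sum of clinical-outcome utilities.

    ``probabilities`` must sum to one and ``utilities`` must lie in [0, 1];
    both are aligned with the same outcome list.
    """
    prob = np.asarray(probabilities, dtype=float)
    util = np.asarray(utilities, dtype=float)
    if prob.shape != util.shape:
        raise ValueError(
            f"mismatched outcome sets: {prob.shape} probabilities vs "
            f"{util.shape} utilities"
        )
    if abs(prob.sum() - 1.0) > 1e-9:
        raise ValueError("outcome probabilities do not sum to 1")
    if util.min() < 0.0 or util.max() > 1.0:
        raise ValueError("utilities out of [0, 1]")
    return float(prob @ util)
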