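"""Qualitative utility modelling and uniform sampling on the utility polytope.

Clinical outcomes are grouped into 16 utility classes: the cross of the two
benefit states (reduced vs standard relapse) with eight adverse-event
classes (no adverse event, non-serious, life-threatening, three grades of
persistent disability, and two lethal classes distinguished by the expected
manner of death).  Instead of eliciting numeric utilities, each class
utility starts as a standard uniform variable and qualitative relations --
strict orderings between classes plus a minimum utility difference ``delta``
between the non-lethal and lethal blocks -- restrict the joint distribution.
Formally, the target is the i.i.d.-uniform joint conditioned on the
constraints, i.e. the uniform distribution on the resulting convex polytope
inside the unit cube, sampled here with a coordinate-wise Gibbs sweep.

The relation set depends on the severity of the relapse at onset (EDSS 4 or
EDSS 5): a patient starting at EDSS 5 gives up more by forgoing improvement,
which is expressed through different diagonal relations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from .tree_model import (
    NO_AE,
    NON_SERIOUS,
    BenefitState,
    ClinicalOutcome,
    SeriousOutcome,
)

__all__ = [
    "AEClass",
    "ConstraintSystem",
    "UtilityDraws",
    "assign_utility_class",
    "class_label",
    "outcome_class_label",
    "build_constraints",
    "feasible_point",
    "gibbs_sample",
    "gamble_indifference",
]


class AEClass(str, enum.Enum):
    """Adverse-event component of a utility class, best to worst."""

    NO_AE = "NO_AE"
    NON_SERIOUS = "NON_SERIOUS"
    LIFE_THREAT = "LIFE_THREAT"
    PERS_MILD = "PERS_MILD"
    PERS_INT = "PERS_INT"
    PERS_SEVERE = "PERS_SEVERE"
    LETHAL_QUICK = "LETHAL_QUICK"
    LETHAL_PAINFUL = "LETHAL_PAINFUL"


#: Vertical desirability order within a benefit state, best first.
AE_CLASS_ORDER: tuple[AEClass, ...] = tuple(AEClass)

LETHAL_AE_CLASSES = frozenset({AEClass.LETHAL_QUICK, AEClass.LETHAL_PAINFUL})

# Persistent-disability grading of the included effects.  Osteonecrosis and
# diabetes are generally manageable and unlikely to stem from a
# life-threatening triggering event; persistent cardio-pulmonary distress,
# arrhythmia sequelae and seizures sit at the severe end; the rest
# (psychosis, myopathy, hepatotoxicity, GI haemorrhage) are intermediate.
PERSISTENT_MILD = frozenset({"Osteonecrosis", "Diabetes"})
PERSISTENT_SEVERE = frozenset(
    {"Cardio-pulmonary distress", "Ventricular arrhythmia/cardiac arrest", "Seizure"}
)

# Manner-of-death grouping: anaphylaxis and cardiac arrest are quick with
# little suffering; deaths from pancreatitis, cardio-pulmonary distress or
# GI haemorrhage are protracted and painful.  Lethal diabetes, hepatotoxicity
# and seizure follow a protracted clinical course and default to the painful
# group; the mapping is exposed for reconfiguration.
LETHAL_QUICK_EFFECTS = frozenset(
    {"Acute severe allergy", "Ventricular arrhythmia/cardiac arrest"}
)


def assign_utility_class(
    effect: str,
    outcome: SeriousOutcome,
    lethal_quick_effects: frozenset[str] = LETHAL_QUICK_EFFECTS,
    persistent_mild: frozenset[str] = PERSISTENT_MILD,
    persistent_severe: frozenset[str] = PERSISTENT_SEVERE,
) -> AEClass:
    """Utility class of one serious effect-outcome combination."""
    if outcome is SeriousOutcome.LIFE_THREATENING:
        return AEClass.LIFE_THREAT
    if outcome is SeriousOutcome.PERSISTENT:
        if effect in persistent_mild:
            return AEClass.PERS_MILD
        if effect in persistent_severe:
            return AEClass.PERS_SEVERE
        return AEClass.PERS_INT
    if outcome is SeriousOutcome.DEATH:
        return AEClass.LETHAL_QUICK if effect in lethal_quick_effects else AEClass.LETHAL_PAINFUL
    raise ValueError(f"unknown outcome {outcome!r}")


def class_label(benefit: BenefitState, ae_class: AEClass) -> str:
    return f"{benefit.value}:{ae_class.value}"


def outcome_class_label(outcome: ClinicalOutcome) -> str:
    """Utility-class label of a clinical outcome."""
    if outcome.branch == NO_AE:
        ae = AEClass.NO_AE
    elif outcome.branch == NON_SERIOUS:
        ae = AEClass.NON_SERIOUS
    else:
        ae = assign_utility_class(outcome.branch, outcome.outcome)
    return class_label(outcome.benefit, ae)


@dataclass(frozen=True)
class ConstraintSystem:
    """Strict-order constraints plus a block gap on unit-cube utilities.

    ``edges`` are (worse, better) label pairs; every utility in
    ``lethal`` must sit at least ``min_diff`` below every utility outside it.
    The class is generic over label sets so small systems can be built for
    validation; :func:`build_constraints` produces the full 16-class system.
    """

    labels: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    lethal: frozenset[str] = frozenset()
    min_diff: float = 0.0
    edss_level: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_diff <= 0.99):
            raise ValueError("minimum utility difference must lie in [0, 0.99]")
        known = set(self.labels)
        for worse, better in self.edges:
            if worse not in known or better not in known:
                raise ValueError(f"edge ({worse}, {better}) uses unknown labels")
        if not self.lethal <= known:
            raise ValueError("lethal block contains unknown labels")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.edges)
        return g

    def satisfied(self, values: Mapping[str, float], tol: float = 0.0) -> bool:
        """Check one utility assignment against every constraint."""
        if any(not (0.0 - tol <= values[c] <= 1.0 + tol) for c in self.labels):
            return False
        for worse, better in self.edges:
            if not values[worse] < values[better] + tol:
                return False
        if self.lethal and len(self.lethal) < len(self.labels):
            max_lethal = max(values[c] for c in self.lethal)
            min_other = min(values[c] for c in self.labels if c not in self.lethal)
            if not min_other >= max_lethal + self.min_diff - tol:
                return False
        return True


def build_constraints(edss_level: int, min_diff: float = 0.0) -> ConstraintSystem:
    """Full 16-class constraint system for a given relapse severity.

    Relations:

    * vertically, within each benefit state, the adverse-event classes are
      totally ordered from NO_AE (best) down to LETHAL_PAINFUL (worst);
    * horizontally, a reduced relapse beats a standard relapse at the same
      adverse-event class;
    * a reduced relapse with a non-serious adverse event beats a standard
      relapse with none (the benefit persists for the whole relapse, the
      nuisance is transient);
    * every non-lethal class utility exceeds every lethal one by at least
      ``min_diff``;
    * at EDSS 4, foregoing the modest improvement to EDSS 3 is preferred to
      gaining it together with a life-threatening event, and likewise a
      standard relapse with mild persistent disability is preferred to a
      reduced relapse with severe persistent disability;
    * at EDSS 5, a standard relapse with a non-serious event is preferred to
      the improvement to EDSS 4 with an intermediate persistent disability.
    """
    if edss_level not in (4, 5):
        raise ValueError("relapse severity must be EDSS 4 or 5")
    labels = tuple(
        class_label(b, c) for b in (BenefitState.REDUCED, BenefitState.STANDARD) for c in AE_CLASS_ORDER
    )
    edges: list[tuple[str, str]] = []
    for b in (BenefitState.REDUCED, BenefitState.STANDARD):
        for worse, better in zip(AE_CLASS_ORDER[1:], AE_CLASS_ORDER[:-1]):
            edges.append((class_label(b, worse), class_label(b, better)))
    for c in AE_CLASS_ORDER:
        edges.append((class_label(BenefitState.STANDARD, c), class_label(BenefitState.REDUCED, c)))
    R, S = BenefitState.REDUCED, BenefitState.STANDARD
    edges.append((class_label(S, AEClass.NO_AE), class_label(R, AEClass.NON_SERIOUS)))
    if edss_level == 4:
        edges.append((class_label(R, AEClass.LIFE_THREAT), class_label(S, AEClass.NON_SERIOUS)))
        edges.append((class_label(R, AEClass.PERS_SEVERE), class_label(S, AEClass.PERS_MILD)))
    else:
        edges.append((class_label(R, AEClass.PERS_INT), class_label(S, AEClass.NON_SERIOUS)))
    lethal = frozenset(
        class_label(b, c) for b in (R, S) for c in LETHAL_AE_CLASSES
    )
    system = ConstraintSystem(labels, tuple(edges), lethal, min_diff, edss_level)
    _check_feasibility(system)
    return system


def _check_feasibility(system: ConstraintSystem) -> None:
    g = system.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"constraint system is cyclic: {cycle}")
    if system.lethal and len(system.lethal) < len(system.labels):
        for worse, better in system.edges:
            if worse not in system.lethal and better in system.lethal:
                raise ValueError(
                    f"edge ({worse}, {better}) places a non-lethal class below "
                    "the lethal block; infeasible with the block gap"
                )


def feasible_point(system: ConstraintSystem) -> dict[str, float]:
    """One utility assignment satisfying every constraint.

    Classes are spaced evenly along a topological order, with the lethal
    block compressed below the ``min_diff`` gap.
    """
    _check_feasibility(system)
    order = list(nx.topological_sort(system.graph()))
    rank = {c: i for i, c in enumerate(order)}
    lethal = sorted(system.lethal, key=rank.__getitem__)
    other = sorted((c for c in system.labels if c not in system.lethal), key=rank.__getitem__)
    values: dict[str, float] = {}
    if lethal and other:
        eps = (1.0 - system.min_diff) / (len(system.labels) + 2)
        for i, c in enumerate(lethal):
            values[c] = eps * (i + 1)
        base = eps * len(lethal) + system.min_diff
        for j, c in enumerate(other):
            values[c] = base + eps * (j + 1)
    else:
        eps = 1.0 / (len(system.labels) + 1)
        for i, c in enumerate(lethal + other if lethal else other):
            values[c] = eps * (i + 1)
    assert system.satisfied(values, tol=1e-12)
    return values


@dataclass
class UtilityDraws:
    """Matrix of sampled class utilities, one row per retained sweep."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n_classes)
    system: ConstraintSystem
    seed: int | None
    burn_in: int
    thin: int

    def __len__(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]


def gibbs_sample(
    system: ConstraintSystem,
    n: int,
    burn_in: int = 1_000,
    thin: int = 5,
    seed: int | np.random.SeedSequence | None = None,
) -> UtilityDraws:
    """Uniform sampling on the constraint polytope by coordinate-wise Gibbs.

    Each sweep resamples every class utility uniformly on the interval its
    neighbours and the block gap allow; the conditional of a uniform joint
    on a polytope is exactly uniform on that interval, so the chain targets
    the uniform distribution on the polytope.  Starts at a feasible point;
    keeps ``n`` rows after ``burn_in`` sweeps, one every ``thin`` sweeps.
    """
    if n < 1 or burn_in < 0 or thin < 1:
        raise ValueError("need n >= 1, burn_in >= 0, thin >= 1")
    start = feasible_point(system)  # raises on infeasible systems
    labels = system.labels
    k = len(labels)
    idx = {c: i for i, c in enumerate(labels)}
    preds: list[list[int]] = [[] for _ in range(k)]
    succs: list[list[int]] = [[] for _ in range(k)]
    for worse, better in system.edges:
        preds[idx[better]].append(idx[worse])
        succs[idx[worse]].append(idx[better])
    lethal_idx = [idx[c] for c in labels if c in system.lethal]
    other_idx = [idx[c] for c in labels if c not in system.lethal]
    is_lethal = [c in system.lethal for c in labels]
    block = bool(lethal_idx) and bool(other_idx)
    delta = system.min_diff

    u = [start[c] for c in labels]
    n_sweeps = burn_in + n * thin
    rng = np.random.default_rng(seed)
    uniforms = rng.random((n_sweeps, k)).tolist()
    out = np.empty((n, k))
    kept = 0
    for s in range(n_sweeps):
        row = uniforms[s]
        for i in range(k):
            lo = 0.0
            hi = 1.0
            for j in preds[i]:
                if u[j] > lo:
                    lo = u[j]
            for j in succs[i]:
                if u[j] < hi:
                    hi = u[j]
            if block:
                if is_lethal[i]:
                    m = min(u[j] for j in other_idx) - delta
                    if m < hi:
                        hi = m
                else:
                    m = max(u[j] for j in lethal_idx) + delta
                    if m > lo:
                        lo = m
            u[i] = lo + row[i] * (hi - lo)
        if s >= burn_in and (s - burn_in) % thin == thin - 1:
            out[kept] = u
            kept += 1
    assert kept == n
    return UtilityDraws(
        labels=labels,
        values=out,
        system=system,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        burn_in=burn_in,
        thin=thin,
    )


def gamble_indifference(draws: UtilityDraws) -> float:
    """Indifference probability interpreting the minimum utility difference.

    For each draw, the probability of the worst outcome at which the typical
    patient is indifferent between the status quo (standard relapse, no
    adverse event) and a gamble between the best outcome (reduced relapse,
    no adverse event) and the worst (protracted lethal outcome):
    ``(u_best - u_statusquo) / (u_best - u_worst)``.  Returns the median
    over draws; draws with ``u_best == u_worst`` are excluded.
    """
    u_best = draws.column(class_label(BenefitState.REDUCED, AEClass.NO_AE))
    u_sq = draws.column(class_label(BenefitState.STANDARD, AEClass.NO_AE))
    worst = np.minimum(
        draws.column(class_label(BenefitState.REDUCED, AEClass.LETHAL_PAINFUL)),
        draws.column(class_label(BenefitState.STANDARD, AEClass.LETHAL_PAINFUL)),
    )
    span = u_best - worst
    valid = span > 0
    if not np.any(valid):
        raise ValueError("no draws with distinct best and worst utilities")
    return float(np.median((u_best[valid] - u_sq[valid]) / span[valid]))
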