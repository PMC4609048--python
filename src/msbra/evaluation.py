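"""Monte-Carlo evaluation: expected utilities, preference rates, grids.

One scenario fixes the serious-risk interval distribution, the background
proportion ``pi``, the minimum utility difference ``delta`` and the relapse
severity (EDSS level), then runs ``n_iterations`` joint draws of every
probability and utility variable.  Per iteration and alternative the
expected utility is the probability-weighted sum of the 56 clinical-outcome
utilities; the preference rate of an alternative is the fraction of
iterations in which it attains the highest expected utility.

Coupling across alternatives follows the inferential structure of the
assessment: effectiveness and non-serious-risk draws are paired across
alternatives by iteration index (comparisons must be made within an
iteration before aggregating); serious risks are drawn independently per
active alternative and combination, with the no-treatment value derived
from both via the background proportion; one utility row per iteration is
shared by all alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._seeds import stream_rng, substream
from .effectiveness_meta import (
    PosteriorDraws,
    fit_metropolis,
    posterior_probability_draws,
    sample_low_dose_nonserious,
)
from .serious_risks import (
    RiskDistributionSpec,
    RiskFamily,
    background_risk,
    effective_limits,
    sample_risk,
)
from .synthetic_data import PLACEBO, StudyFixtures, study_fixtures
from .tree_model import ALTERNATIVES, Alternative, DecisionTree, build_tree
from .utility_model import UtilityDraws, build_constraints, gibbs_sample, outcome_class_label

__all__ = [
    "ScenarioConfig",
    "GridSpec",
    "PosteriorSet",
    "ScenarioResult",
    "GridResult",
    "fit_all_posteriors",
    "run_scenario",
    "preference_rates",
    "eu_differences",
    "run_grid",
    "fix_variable_analysis",
    "DEFAULT_RISK_FAMILIES",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Settings of one probabilistic-analysis scenario."""

    risk_spec: RiskDistributionSpec = RiskDistributionSpec(RiskFamily.UNIFORM)
    background_proportion: float = 0.0
    min_utility_difference: float = 0.0
    edss_level: int = 4
    n_iterations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_proportion <= 0.5):
            raise ValueError("background proportion must lie in [0, 0.5]")
        if not (0.0 <= self.min_utility_difference <= 0.99):
            raise ValueError("minimum utility difference must lie in [0, 0.99]")
        if self.edss_level not in (4, 5):
            raise ValueError("EDSS level must be 4 or 5")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")


#: The four interval-distribution families of the sensitivity grid.
DEFAULT_RISK_FAMILIES: tuple[RiskDistributionSpec, ...] = (
    RiskDistributionSpec(RiskFamily.UNIFORM),
    RiskDistributionSpec(RiskFamily.TRUNC_EXP, 5.0),
    RiskDistributionSpec(RiskFamily.TRUNC_EXP, 50.0),
    RiskDistributionSpec(RiskFamily.TRUNC_EXP, 500.0),
)


@dataclass(frozen=True)
class GridSpec:
    """Enumeration of sensitivity-analysis cells."""

    risk_specs: tuple[RiskDistributionSpec, ...] = DEFAULT_RISK_FAMILIES
    background_proportions: tuple[float, ...] = (0.0, 0.10, 0.25, 0.50)
    min_utility_differences: tuple[float, ...] = (
        0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99,
    )
    edss_levels: tuple[int, ...] = (4, 5)
    n_iterations: int = 10_000

    @property
    def n_cells(self) -> int:
        return (
            len(self.risk_specs)
            * len(self.background_proportions)
            * len(self.min_utility_differences)
            * len(self.edss_levels)
        )


@dataclass
class PosteriorSet:
    """Fitted posteriors feeding the evaluation.

    Effectiveness posteriors for high dose, low dose and placebo (the
    no-treatment proxy); non-serious-risk posteriors for high dose and
    placebo (the low-dose value is interpolated at evaluation time).
    """

    effectiveness: dict[str, PosteriorDraws]
    nonserious: dict[str, PosteriorDraws]

    def min_draws(self) -> int:
        return min(len(p) for p in (*self.effectiveness.values(), *self.nonserious.values()))


def fit_all_posteriors(
    seed: int,
    fixtures: StudyFixtures | None = None,
    n_iter: int = 55_000,
    burn_in: int = 5_000,
) -> PosteriorSet:
    """Fit the five meta-analytic models on the packaged arm tables.

    Each fit uses its own named seed stream derived from ``seed``.
    """
    fx = fixtures if fixtures is not None else study_fixtures()
    eff = {}
    for alt in (Alternative.HIGH_DOSE.value, Alternative.LOW_DOSE.value, PLACEBO):
        eff[alt] = fit_metropolis(
            fx.effectiveness_arms[alt],
            n_iter=n_iter,
            burn_in=burn_in,
            seed=substream(seed, "fit-effectiveness", alt),
            label=f"effectiveness/{alt}",
        )
    ns = {}
    for alt in (Alternative.HIGH_DOSE.value, PLACEBO):
        ns[alt] = fit_metropolis(
            fx.nonserious_arms[alt],
            n_iter=n_iter,
            burn_in=burn_in,
            seed=substream(seed, "fit-nonserious", alt),
            label=f"nonserious/{alt}",
        )
    return PosteriorSet(effectiveness=eff, nonserious=ns)


@dataclass
class ScenarioResult:
    """All draws and summaries of one evaluated scenario.

    Array columns follow ``ALTERNATIVES`` order (high dose, low dose, no
    treatment).  ``serious`` is (n, n_combinations, 3); ``utilities`` holds
    the 16 class-utility columns named by ``utility_labels``.
    """

    config: ScenarioConfig
    tree: DecisionTree
    effectiveness: np.ndarray  # (n, 3)
    nonserious: np.ndarray  # (n, 3)
    serious: np.ndarray  # (n, k, 3)
    utilities: np.ndarray  # (n, 16)
    utility_labels: tuple[str, ...]
    expected_utilities: np.ndarray = field(default=None)  # (n, 3)
    rates: np.ndarray = field(default=None)  # (3,)

    @property
    def preference_rates(self) -> dict[str, float]:
        return {alt.value: float(r) for alt, r in zip(ALTERNATIVES, self.rates)}

    @property
    def median_expected_utilities(self) -> dict[str, float]:
        med = np.median(self.expected_utilities, axis=0)
        return {alt.value: float(m) for alt, m in zip(ALTERNATIVES, med)}

    def summary(self) -> pd.DataFrame:
        med = np.median(self.expected_utilities, axis=0)
        return pd.DataFrame(
            {
                "alternative": [a.value for a in ALTERNATIVES],
                "preference_rate": self.rates,
                "median_expected_utility": med,
            }
        )


def _subsample(draws: PosteriorDraws, n: int, allow_resample: bool = False) -> np.ndarray:
    """Evenly spaced subsample of the posterior stream (deterministic)."""
    values = posterior_probability_draws(draws)
    if len(values) < n:
        if not allow_resample:
            raise ValueError(
                f"posterior {draws.label or ''} has {len(values)} draws; "
                f"{n} required (pass allow_resample=True to recycle)"
            )
        reps = -(-n // len(values))
        values = np.tile(values, reps)
    idx = np.linspace(0, len(values) - 1, n).round().astype(int)
    return values[idx]


def _evaluate_draws(
    tree: DecisionTree,
    class_columns: np.ndarray,
    e: np.ndarray,
    r: np.ndarray,
    q: np.ndarray,
    u_classes: np.ndarray,
) -> np.ndarray:
    """Vectorised expected utilities, (n, 3)."""
    n = e.shape[0]
    u_outcomes = u_classes[:, class_columns]  # (n, 56)
    k = q.shape[1]
    eu = np.empty((n, len(ALTERNATIVES)))
    for a in range(len(ALTERNATIVES)):
        q_a = q[:, :, a]
        sum_q = q_a.sum(axis=1)
        rest = 1.0 - sum_q
        half = np.concatenate(
            [q_a, (rest * r[:, a])[:, None], (rest * (1.0 - r[:, a]))[:, None]], axis=1
        )
        probs = np.concatenate([e[:, a, None] * half, (1.0 - e[:, a, None]) * half], axis=1)
        eu[:, a] = np.einsum("ij,ij->i", probs, u_outcomes)
    return eu


def preference_rates(eu_draws: np.ndarray) -> np.ndarray:
    """Fraction of iterations each alternative attains the highest expected
    utility; exact ties split equally among the tied alternatives."""
    eu = np.asarray(eu_draws, dtype=float)
    if eu.ndim != 2 or eu.shape[0] < 1:
        raise ValueError("need a (n_iterations, n_alternatives) array")
    best = eu.max(axis=1, keepdims=True)
    tied = eu == best
    weights = tied / tied.sum(axis=1, keepdims=True)
    return weights.mean(axis=0)


def eu_differences(eu_draws: np.ndarray, alternative: int | Alternative) -> np.ndarray:
    """Per-iteration difference between one alternative's expected utility
    and the best of the other alternatives."""
    eu = np.asarray(eu_draws, dtype=float)
    a = ALTERNATIVES.index(alternative) if isinstance(alternative, Alternative) else int(alternative)
    others = np.delete(eu, a, axis=1)
    return eu[:, a] - others.max(axis=1)


def run_scenario(
    posteriors: PosteriorSet,
    fixtures: StudyFixtures,
    config: ScenarioConfig,
    allow_resample: bool = False,
    utility_draws: UtilityDraws | None = None,
    active_serious: np.ndarray | None = None,
) -> ScenarioResult:
    """Evaluate one scenario.

    ``utility_draws`` and ``active_serious`` allow a grid driver to share
    draws between cells whose generating seeds coincide; when omitted they
    are generated here from the scenario's named seed streams.
    """
    n = config.n_iterations
    tree = build_tree(fixtures.effects)
    limits = effective_limits(fixtures.risk_limit_table)

    HIGH, LOW = Alternative.HIGH_DOSE.value, Alternative.LOW_DOSE.value
    e = np.column_stack(
        [
            _subsample(posteriors.effectiveness[HIGH], n, allow_resample),
            _subsample(posteriors.effectiveness[LOW], n, allow_resample),
            _subsample(posteriors.effectiveness[PLACEBO], n, allow_resample),
        ]
    )
    r_high = _subsample(posteriors.nonserious[HIGH], n, allow_resample)
    r_none = _subsample(posteriors.nonserious[PLACEBO], n, allow_resample)
    r_low = sample_low_dose_nonserious(
        r_none, r_high, seed=stream_rng(config.seed, "lowdose-interpolation")
    )
    r = np.column_stack([r_high, r_low, r_none])

    if active_serious is None:
        active_serious = sample_active_serious(
            limits, tree, config.risk_spec, n, substream(config.seed, "risks", config.risk_spec.name())
        )
    q = np.empty((n, tree.n_combinations, 3))
    q[:, :, 0] = active_serious[:, :, 1]  # high dose
    q[:, :, 1] = active_serious[:, :, 0]  # low dose
    q[:, :, 2] = background_risk(
        active_serious[:, :, 0], active_serious[:, :, 1], config.background_proportion
    )

    if utility_draws is None:
        system = build_constraints(config.edss_level, config.min_utility_difference)
        utility_draws = gibbs_sample(
            system,
            n,
            seed=substream(
                config.seed,
                "utilities",
                config.edss_level,
                round(config.min_utility_difference, 6),
            ),
        )
    if len(utility_draws) < n:
        raise ValueError("insufficient utility draws for the requested iterations")
    u_classes = utility_draws.values[:n]
    label_index = {lab: i for i, lab in enumerate(utility_draws.labels)}
    class_columns = np.array(
        [label_index[outcome_class_label(o)] for o in tree.outcomes], dtype=int
    )

    eu = _evaluate_draws(tree, class_columns, e, r, q, u_classes)
    result = ScenarioResult(
        config=config,
        tree=tree,
        effectiveness=e,
        nonserious=r,
        serious=q,
        utilities=u_classes,
        utility_labels=utility_draws.labels,
        expected_utilities=eu,
        rates=preference_rates(eu),
    )
    return result


def sample_active_serious(
    limits: Mapping,
    tree: DecisionTree,
    risk_spec: RiskDistributionSpec,
    n: int,
    seed,
) -> np.ndarray:
    """Serious-risk draws for the two active alternatives, (n, k, 2).

    Column 0 is low dose, column 1 high dose; draws are independent across
    combinations and alternatives.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n, tree.n_combinations, 2))
    for i, combo in enumerate(tree.combinations):
        lim = limits[combo]
        out[:, i, 0] = sample_risk(lim[Alternative.LOW_DOSE], risk_spec, n, rng)
        out[:, i, 1] = sample_risk(lim[Alternative.HIGH_DOSE], risk_spec, n, rng)
    return out


@dataclass
class GridResult:
    """Preference-rate summaries over the sensitivity grid."""

    table: pd.DataFrame
    spec: GridSpec
    seed: int

    def max_rate(self, alternative: Alternative) -> float:
        return float(self.table[f"rate_{alternative.value}"].max())

    def preferred_fraction(self, alternative: Alternative) -> float:
        """Fraction of cells in which the alternative has the top rate."""
        cols = [f"rate_{a.value}" for a in ALTERNATIVES]
        rates = self.table[cols].to_numpy()
        target = ALTERNATIVES.index(alternative)
        best = rates.max(axis=1)
        return float(np.mean(rates[:, target] >= best))


def run_grid(
    posteriors: PosteriorSet,
    fixtures: StudyFixtures,
    spec: GridSpec,
    base_seed: int,
    allow_resample: bool = False,
) -> GridResult:
    """One scenario per grid cell, with per-component derived seeds.

    Utility draws depend only on (delta, EDSS) and serious-risk draws only
    on the interval-distribution family, so those streams are generated once
    per distinct setting and shared across the cells they seed identically.
    """
    tree = build_tree(fixtures.effects)
    limits = effective_limits(fixtures.risk_limit_table)
    n = spec.n_iterations

    utility_cache: dict[tuple[int, float], UtilityDraws] = {}
    serious_cache: dict[str, np.ndarray] = {}
    rows = []
    for risk_spec in spec.risk_specs:
        key = risk_spec.name()
        if key not in serious_cache:
            serious_cache[key] = sample_active_serious(
                limits, tree, risk_spec, n, substream(base_seed, "risks", key)
            )
        for pi in spec.background_proportions:
            for delta in spec.min_utility_differences:
                for edss in spec.edss_levels:
                    ukey = (edss, round(delta, 6))
                    if ukey not in utility_cache:
                        system = build_constraints(edss, delta)
                        utility_cache[ukey] = gibbs_sample(
                            system,
                            n,
                            seed=substream(base_seed, "utilities", edss, round(delta, 6)),
                        )
                    config = ScenarioConfig(
                        risk_spec=risk_spec,
                        background_proportion=pi,
                        min_utility_difference=delta,
                        edss_level=edss,
                        n_iterations=n,
                        seed=base_seed,
                    )
                    result = run_scenario(
                        posteriors,
                        fixtures,
                        config,
                        allow_resample=allow_resample,
                        utility_draws=utility_cache[ukey],
                        active_serious=serious_cache[key],
                    )
                    row = {
                        "risk_family": key,
                        "background_proportion": pi,
                        "min_utility_difference": delta,
                        "edss_level": edss,
                    }
                    med = np.median(result.expected_utilities, axis=0)
                    for j, alt in enumerate(ALTERNATIVES):
                        row[f"rate_{alt.value}"] = result.rates[j]
                        row[f"median_eu_{alt.value}"] = med[j]
                    rows.append(row)
    return GridResult(table=pd.DataFrame(rows), spec=spec, seed=base_seed)


#: Recognised variable classes for the uncertainty-attribution analysis.
_FIXABLE = {"probabilities", "utilities", "all", "effectiveness", "nonserious", "serious"}


def fix_variable_analysis(result: ScenarioResult, variable_class: str) -> ScenarioResult:
    """Re-evaluate a scenario with one variable class fixed at its medians.

    Every sampled value of the named class (``probabilities``, ``utilities``,
    ``all``, or one of ``effectiveness`` / ``nonserious`` / ``serious``) is
    replaced by the per-variable median of its draws; all other draws are
    left untouched.  Quantifies how much of the preference-rate spread that
    class of variables contributes.
    """
    if variable_class not in _FIXABLE:
        raise ValueError(
            f"unknown variable class {variable_class!r}; expected one of {sorted(_FIXABLE)}"
        )
    e = result.effectiveness.copy()
    r = result.nonserious.copy()
    q = result.serious.copy()
    u = result.utilities.copy()
    if variable_class in ("probabilities", "all", "effectiveness"):
        e[:] = np.median(e, axis=0, keepdims=True)
    if variable_class in ("probabilities", "all", "nonserious"):
        r[:] = np.median(r, axis=0, keepdims=True)
    if variable_class in ("probabilities", "all", "serious"):
        q[:] = np.median(q, axis=0, keepdims=True)
    if variable_class in ("utilities", "all"):
        u[:] = np.median(u, axis=0, keepdims=True)

    label_index = {lab: i for i, lab in enumerate(result.utility_labels)}
    class_columns = np.array(
        [label_index[outcome_class_label(o)] for o in result.tree.outcomes], dtype=int
    )
    eu = _evaluate_draws(result.tree, class_columns, e, r, q, u)
    return ScenarioResult(
        config=result.config,
        tree=result.tree,
        effectiveness=e,
        nonserious=r,
        serious=q,
        utilities=u,
        utility_labels=result.utility_labels,
        expected_utilities=eu,
        rates=preference_rates(eu),
    )
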