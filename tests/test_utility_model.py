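import numpy as np
import pytest
from scipy import stats

from msbra.tree_model import BenefitState, SeriousOutcome
from msbra.utility_model import (
    AEClass,
    ConstraintSystem,
    assign_utility_class,
    build_constraints,
    class_label,
    feasible_point,
    gamble_indifference,
    gibbs_sample,
)

D, P, LT = SeriousOutcome.DEATH, SeriousOutcome.PERSISTENT, SeriousOutcome.LIFE_THREATENING
R, S = BenefitState.REDUCED, BenefitState.STANDARD


def check_constraints(system, values, tol=0.0):
    """Independent constraint checker (plain loops, no reuse of the class)."""
    ok = all(0.0 <= values[c] <= 1.0 for c in system.labels)
    for worse, better in system.edges:
        ok = ok and values[worse] < values[better] + tol
    lethal = [values[c] for c in system.lethal]
    other = [values[c] for c in system.labels if c not in system.lethal]
    if lethal and other:
        ok = ok and min(other) >= max(lethal) + system.min_diff - tol
    return ok


class TestAssignUtilityClass:
    @pytest.mark.parametrize(
        "effect,outcome,expected",
        [
            ("Psychosis", P, AEClass.PERS_INT),
            ("Acute severe allergy", D, AEClass.LETHAL_QUICK),
            ("Osteonecrosis", P, AEClass.PERS_MILD),
            ("Diabetes", P, AEClass.PERS_MILD),
            ("Seizure", P, AEClass.PERS_SEVERE),
            ("Cardio-pulmonary distress", P, AEClass.PERS_SEVERE),
            ("Pancreatitis", D, AEClass.LETHAL_PAINFUL),
            ("Ventricular arrhythmia/cardiac arrest", D, AEClass.LETHAL_QUICK),
            ("Hepatotoxicity", D, AEClass.LETHAL_PAINFUL),
            ("Myopathy", LT, AEClass.LIFE_THREAT),
        ],
    )
    def test_grouping(self, effect, outcome, expected):
        assert assign_utility_class(effect, outcome) is expected

    def test_every_included_combination_maps_to_one_class(self, fixtures):
        classes = [
            assign_utility_class(spec.name, o)
            for spec in fixtures.effects
            for o in spec.included_outcomes
        ]
        assert len(classes) == 26
        assert set(classes) <= set(AEClass)


class TestBuildConstraints:
    @pytest.mark.parametrize("edss", [4, 5])
    @pytest.mark.parametrize("delta", [0.0, 0.4, 0.99])
    def test_systems_are_acyclic_and_feasible(self, edss, delta):
        system = build_constraints(edss, delta)
        assert len(system.labels) == 16
        point = feasible_point(system)
        assert check_constraints(system, point, tol=1e-12)

    def test_edss4_has_its_two_extra_diagonals(self):
        sys4 = build_constraints(4)
        assert (class_label(R, AEClass.LIFE_THREAT), class_label(S, AEClass.NON_SERIOUS)) in sys4.edges
        assert (class_label(R, AEClass.PERS_SEVERE), class_label(S, AEClass.PERS_MILD)) in sys4.edges

    def test_edss5_has_its_extra_diagonal(self):
        sys5 = build_constraints(5)
        assert (class_label(R, AEClass.PERS_INT), class_label(S, AEClass.NON_SERIOUS)) in sys5.edges

    def test_contradictory_edges_rejected(self):
        system = ConstraintSystem(("a", "b"), (("a", "b"), ("b", "a")))
        with pytest.raises(ValueError, match="cyclic"):
            feasible_point(system)

    def test_nonlethal_below_lethal_block_rejected(self):
        system = ConstraintSystem(
            ("a", "b"), (("b", "a"),), lethal=frozenset({"a"}), min_diff=0.2
        )
        with pytest.raises(ValueError, match="block"):
            feasible_point(system)

    def test_delta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_constraints(4, 1.2)


class TestGibbs:
    def test_two_class_chain_marginal_means(self):
        """Uniform on {u_a < u_b}: means are (1/3, 2/3)."""
        system = ConstraintSystem(("a", "b"), (("a", "b"),))
        draws = gibbs_sample(system, 50_000, burn_in=200, thin=1, seed=1)
        assert draws.column("a").mean() == pytest.approx(1 / 3, abs=0.01)
        assert draws.column("b").mean() == pytest.approx(2 / 3, abs=0.01)

    def test_two_class_gap_marginal_means(self):
        """Uniform on {u_a + 0.4 <= u_b}: means are (0.2, 0.8)."""
        system = ConstraintSystem(("a", "b"), (), lethal=frozenset({"a"}), min_diff=0.4)
        draws = gibbs_sample(system, 50_000, burn_in=200, thin=1, seed=2)
        assert draws.column("a").mean() == pytest.approx(0.2, abs=0.01)
        assert draws.column("b").mean() == pytest.approx(0.8, abs=0.01)

    @pytest.mark.parametrize("edss,delta", [(4, 0.0), (4, 0.4), (5, 0.99)])
    def test_every_draw_satisfies_every_constraint(self, edss, delta):
        system = build_constraints(edss, delta)
        draws = gibbs_sample(system, 2_000, seed=3)
        for row in draws.values:
            values = dict(zip(draws.labels, row))
            assert check_constraints(system, values, tol=1e-12)

    def test_gibbs_matches_rejection_sampling_small_system(self):
        """Per-coordinate CDFs agree with plain rejection sampling (KS < 0.02)."""
        labels = ("v", "w", "x", "y")
        system = ConstraintSystem(
            labels,
            (("v", "w"), ("w", "x"), ("v", "y")),
            lethal=frozenset({"v"}),
            min_diff=0.3,
        )
        draws = gibbs_sample(system, 20_000, burn_in=500, thin=2, seed=4)
        rng = np.random.default_rng(5)
        accepted = []
        while len(accepted) < 20_000:
            block = rng.random((200_000, 4))
            ok = (
                (block[:, 0] < block[:, 1])
                & (block[:, 1] < block[:, 2])
                & (block[:, 0] < block[:, 3])
                & (np.minimum(block[:, 1], np.minimum(block[:, 2], block[:, 3])) >= block[:, 0] + 0.3)
            )
            accepted.extend(block[ok])
        rejection = np.array(accepted[:20_000])
        for i in range(4):
            ks = stats.ks_2samp(draws.values[:, i], rejection[:, i]).statistic
            assert ks < 0.02, labels[i]

    def test_reduced_dominates_standard_stochastically(self):
        system = build_constraints(4, 0.25)
        draws = gibbs_sample(system, 5_000, seed=6)
        grid = np.linspace(0, 1, 21)
        for ae in AEClass:
            red = draws.column(class_label(R, ae))
            std = draws.column(class_label(S, ae))
            red_cdf = (red[:, None] <= grid).mean(axis=0)
            std_cdf = (std[:, None] <= grid).mean(axis=0)
            assert np.all(red_cdf <= std_cdf + 0.02), ae

    def test_standard_no_ae_worth_less_in_severe_relapse(self):
        """Foregone improvement costs more when the relapse starts at EDSS 5."""
        label = class_label(S, AEClass.NO_AE)
        mean4 = gibbs_sample(build_constraints(4, 0.25), 5_000, seed=7).column(label).mean()
        mean5 = gibbs_sample(build_constraints(5, 0.25), 5_000, seed=8).column(label).mean()
        assert mean5 < mean4

    def test_infeasible_system_rejected_before_sampling(self):
        system = ConstraintSystem(("a", "b"), (("a", "b"), ("b", "a")))
        with pytest.raises(ValueError):
            gibbs_sample(system, 10, seed=0)


class TestGambleIndifference:
    def test_degenerate_arithmetic(self):
        system = build_constraints(4, 0.1)
        draws = gibbs_sample(system, 10, seed=9)
        best = class_label(R, AEClass.NO_AE)
        sq = class_label(S, AEClass.NO_AE)
        for lab in draws.labels:
            i = draws.labels.index(lab)
            if lab == best:
                draws.values[:, i] = 1.0
            elif lab == sq:
                draws.values[:, i] = 0.9
            else:
                draws.values[:, i] = 0.0
        assert gamble_indifference(draws) == pytest.approx(0.1)

    def test_risk_aversion_grows_with_the_minimum_difference(self):
        """A wider lethal gap means a lower acceptable lethal probability;
        around 7 % at delta 0.5 and around 1 % at delta 0.9."""
        d05 = gamble_indifference(gibbs_sample(build_constraints(4, 0.5), 20_000, seed=10))
        d09 = gamble_indifference(gibbs_sample(build_constraints(4, 0.9), 20_000, seed=11))
        assert 0.03 <= d05 <= 0.10
        assert 0.005 <= d09 <= 0.02
        assert d09 < d05
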