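import numpy as np
import pytest
from scipy import stats

from msbra.serious_risks import (
    CaseReport,
    DrugRole,
    RiskDistributionSpec,
    RiskFamily,
    background_risk,
    classify_report,
    compute_upper_limit,
    effective_limits,
    outcome_fraction,
    sample_risk,
    select_combinations,
    truncated_exp_mean,
)
from msbra.tree_model import Alternative, SeriousOutcome

D, P, LT = SeriousOutcome.DEATH, SeriousOutcome.PERSISTENT, SeriousOutcome.LIFE_THREATENING


def _report(role=DrugRole.SUSPECTED, reactions=(("hepatotoxicity", P),), other=False, onset=30, id="r"):
    return CaseReport(
        id=id, drug_role=role, reactions=tuple(reactions), other_drug_implicated=other,
        time_to_onset_days=onset,
    )


class TestClassifyReport:
    def test_hierarchy_within_one_effect(self):
        r = _report(reactions=(("hepatotoxicity", LT), ("hepatotoxicity", P)))
        assert classify_report(r) == {"hepatotoxicity": P}

    def test_death_outranks_everything(self):
        r = _report(reactions=(("seizure", LT), ("seizure", D), ("seizure", P)))
        assert classify_report(r) == {"seizure": D}

    def test_distinct_effects_classified_separately(self):
        r = _report(reactions=(("psychosis", LT), ("seizure", D)))
        assert classify_report(r) == {"psychosis": LT, "seizure": D}

    def test_no_serious_evidence_yields_empty_classification(self):
        r = _report(reactions=(("rash", None),))
        assert classify_report(r) == {}


class TestSelectCombinations:
    @pytest.mark.parametrize(
        "low,high,included", [(2, 0, False), (1, 2, True), (0, 3, True), (1, 1, False)]
    )
    def test_three_report_rule_boundary(self, low, high, included):
        out = select_combinations({("x", D): (low, high)})
        assert (("x", D) in out) is included

    def test_paper_count_table_reconstruction(self, fixtures):
        """Counts engineered at the inclusion threshold reproduce the 26
        included combinations."""
        counts = {}
        for spec in fixtures.effects:
            for o in (D, P, LT):
                n = 3 if o in spec.included_outcomes else 2
                counts[(spec.name, o)] = (1, n - 1)
        assert len(select_combinations(counts)) == 26

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            select_combinations({("x", D): (-1, 5)})


class TestUpperLimit:
    def test_simple_ratio(self):
        reports = [_report(id=f"c{i}") for i in range(3)]
        reports += [_report(reactions=(("other", None),), id=f"n{i}") for i in range(297)]
        lim = compute_upper_limit(reports, "hepatotoxicity", P)
        assert lim.limit == pytest.approx(0.01)

    def test_all_qualifying_gives_one(self):
        reports = [_report(id=f"c{i}") for i in range(5)]
        assert compute_upper_limit(reports, "hepatotoxicity", P).limit == 1.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            compute_upper_limit([], "x", D)

    def test_numerator_filters_match_brute_force_oracle(self):
        """Role/onset/other-drug filters agree with an independent count."""
        rng = np.random.default_rng(8)
        roles = list(DrugRole)
        reports = []
        for i in range(400):
            role = roles[rng.integers(3)]
            onset = None if rng.random() < 0.1 else int(rng.integers(0, 400))
            carries = rng.random() < 0.3
            reactions = (("myopathy", P),) if carries else (("myopathy", LT),)
            reports.append(
                CaseReport(
                    id=f"r{i}", drug_role=role, reactions=reactions,
                    other_drug_implicated=bool(rng.random() < 0.5),
                    time_to_onset_days=onset,
                )
            )
        expected = 0
        for r in reports:  # independent re-statement of the main-text rules
            if r.reactions[0][1] is not P:
                continue
            if r.drug_role is DrugRole.CONCOMITANT and r.other_drug_implicated:
                continue
            if r.time_to_onset_days is None or r.time_to_onset_days > 180:
                continue
            expected += 1
        lim = compute_upper_limit(reports, "myopathy", P)
        assert lim.limit == pytest.approx(expected / 400)

    def test_onset_exemption_admits_late_and_missing_onsets(self):
        reports = [
            _report(onset=365, id="late"),
            _report(onset=None, id="missing"),
            _report(reactions=(("other", None),), id="pad"),
        ]
        strict = compute_upper_limit(reports, "hepatotoxicity", P)
        exempt = compute_upper_limit(reports, "hepatotoxicity", P, exempt_onset_filter=True)
        assert strict.limit == 0.0
        assert exempt.limit == pytest.approx(2 / 3)


class TestSampleRisk:
    def test_uniform_mean_is_half_the_limit(self):
        draws = sample_risk(0.02, RiskDistributionSpec(RiskFamily.UNIFORM), 100_000, seed=1)
        assert draws.mean() == pytest.approx(0.01, rel=0.05)
        assert np.all((draws >= 0) & (draws <= 0.02))

    def test_truncated_exponential_mean_k5(self):
        spec = RiskDistributionSpec(RiskFamily.TRUNC_EXP, 5.0)
        draws = sample_risk(1.0, spec, 100_000, seed=2)
        assert draws.mean() == pytest.approx(0.19, abs=0.005)

    def test_zero_limit_degenerates_to_zero(self):
        spec = RiskDistributionSpec(RiskFamily.TRUNC_EXP, 5.0)
        assert np.all(sample_risk(0.0, spec, 100) == 0.0)

    def test_empirical_cdf_matches_analytic_truncated_exponential(self):
        L, k = 0.05, 5.0
        lam = k / L
        draws = sample_risk(L, RiskDistributionSpec(RiskFamily.TRUNC_EXP, k), 100_000, seed=3)

        def cdf(x):
            return -np.expm1(-lam * np.asarray(x)) / -np.expm1(-lam * L)

        ks = stats.kstest(draws, cdf).statistic
        assert ks < 0.01

    def test_trunc_exp_mean_strictly_decreasing_in_k(self):
        means = []
        for k in (2.0, 5.0, 20.0, 50.0, 500.0):
            spec = RiskDistributionSpec(RiskFamily.TRUNC_EXP, k)
            means.append(sample_risk(0.01, spec, 50_000, seed=4).mean())
        assert all(a > b for a, b in zip(means, means[1:]))


class TestTruncatedExpMean:
    @pytest.mark.parametrize("k,frac", [(5.0, 0.19), (50.0, 0.020), (500.0, 0.0020)])
    def test_published_interval_means(self, k, frac):
        for L in (1.0, 0.02):
            ratio = truncated_exp_mean(L, k) / L
            assert float(f"{ratio:.2g}") == frac

    def test_small_k_limit_is_uniform_mean(self):
        assert truncated_exp_mean(0.6, 1e-8) == pytest.approx(0.3, rel=1e-4)


class TestBackgroundRisk:
    def test_zero_proportion(self):
        assert background_risk(0.02, 0.04, 0.0) == 0.0

    def test_hand_arithmetic(self):
        assert background_risk(0.01, 0.03, 0.5) == pytest.approx(0.01)

    def test_never_exceeds_the_larger_active_risk(self):
        rng = np.random.default_rng(0)
        q1, q2 = rng.random(100), rng.random(100)
        out = background_risk(q1, q2, 0.5)
        assert np.all(out <= np.maximum(q1, q2))

    def test_out_of_range_proportion_rejected(self):
        with pytest.raises(ValueError):
            background_risk(0.1, 0.1, 0.6)


class TestOutcomeFraction:
    def test_hand_example(self):
        assert outcome_fraction([0.01, 0.01, 0.02]) == pytest.approx([0.25, 0.25, 0.5])

    def test_single_outcome(self):
        assert outcome_fraction([0.003]) == pytest.approx([1.0])

    def test_random_vectors_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            q = rng.random(rng.integers(1, 6))
            assert outcome_fraction(q).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            outcome_fraction([0.0, 0.0])


def test_effective_limits_apply_printed_zero_substitution(fixtures):
    lims = effective_limits(fixtures.risk_limit_table)
    assert len(lims) == 26
    # printed 0.00 high-dose limits are replaced by the low-dose limits
    assert lims[("Acute severe allergy", D)][Alternative.HIGH_DOSE] == pytest.approx(0.0024)
    assert lims[("Seizure", P)][Alternative.HIGH_DOSE] == pytest.approx(0.0013)
    # an unflagged cell is taken as printed (percent -> proportion)
    assert lims[("Osteonecrosis", P)][Alternative.HIGH_DOSE] == pytest.approx(0.0158)
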