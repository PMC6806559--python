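import numpy as np
import pandas as pd
import pytest

from ictos.cohort import CohortSpec, generate_cohort
from ictos.survival import (
    PowerSpec,
    compare_arms,
    count_risk_factors,
    interaction_test,
    km_weighted,
    logrank_power,
    required_cohort_size,
    stratify_low_ictos,
)

from .oracles import textbook_km


class TestKaplanMeier:
    def test_two_events_hand_product_limit(self):
        curve = km_weighted([1.0, 2.0], [1, 1])
        assert curve.survival_at(1.0) == pytest.approx(0.5)
        assert curve.survival_at(2.0) == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        curve = km_weighted([3.0, 5.0, 8.0], [0, 0, 0])
        assert curve.no_events
        assert curve.survival_at(100.0) == 1.0

    def test_integer_weights_equal_row_replication(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 30)
        events = rng.binomial(1, 0.7, 30)
        k = rng.integers(1, 4, 30)
        weighted = km_weighted(times, events, k.astype(float))
        replicated = km_weighted(np.repeat(times, k), np.repeat(events, k))
        for t in np.linspace(0.1, 40, 25):
            assert weighted.survival_at(t) == pytest.approx(
                replicated.survival_at(t)
            )

    def test_unit_weights_match_textbook_estimator(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(12, 80)
        events = rng.binomial(1, 0.6, 80)
        curve = km_weighted(times, events)
        for t, s in textbook_km(times, events):
            assert curve.survival_at(t) == pytest.approx(s)

    def test_ci_constant_between_events(self):
        curve = km_weighted([2.0, 4.0, 9.0], [1, 0, 1])
        lo5, hi5 = curve.ci_at(5.0)
        lo8, hi8 = curve.ci_at(8.0)
        assert (lo5, hi5) == (lo8, hi8)  # no event in (4, 9)


class TestCompareArms:
    def test_null_hazard_ratio_near_one(self):
        t = generate_cohort(
            CohortSpec(
                n_patients=4000, true_benefit_coefs=(0, 0, 0),
                base_treatment_loghr=0.0, seed=31,
            )
        ).table
        cmp = compare_arms(t)
        assert cmp.hr == pytest.approx(1.0, abs=0.12)
        assert cmp.hr_ci[0] < 1.0 < cmp.hr_ci[1]

    def test_time_rescaling_leaves_hr_unchanged(self):
        t = generate_cohort(CohortSpec(n_patients=500, seed=32)).table
        a = compare_arms(t)
        b = compare_arms(t.assign(time_months=t["time_months"] / 2.0))
        assert a.hr == pytest.approx(b.hr, rel=1e-6)
        assert a.p_logrank == pytest.approx(b.p_logrank, rel=1e-6)

    def test_single_arm_rejected(self):
        t = generate_cohort(CohortSpec(n_patients=100, seed=33)).table
        with pytest.raises(ValueError, match="both arms"):
            compare_arms(t[t["arm"] == 0])

    def test_known_hazard_ratio_recovered(self):
        t = generate_cohort(
            CohortSpec(
                n_patients=2000, true_benefit_coefs=(0, 0, 0),
                base_treatment_loghr=np.log(0.5), censor_rate=0.0,
                admin_censor_time=1e9, seed=34,
            )
        ).table
        cmp = compare_arms(t)
        assert cmp.hr_ci[0] < 0.5 < cmp.hr_ci[1]


class TestInteraction:
    def test_label_recoding_leaves_p_unchanged(self):
        t = generate_cohort(CohortSpec(n_patients=600, seed=35)).table
        rng = np.random.default_rng(35)
        lab = rng.binomial(1, 0.5, len(t))
        p1 = interaction_test(t, lab)
        p2 = interaction_test(t, np.where(lab == 1, "high", "low"))
        assert p1 == pytest.approx(p2)

    def test_empty_stratum_rejected(self):
        t = generate_cohort(CohortSpec(n_patients=100, seed=36)).table
        lab = (t["arm"].to_numpy() == 1).astype(int)  # label == arm
        with pytest.raises(ValueError, match="empty stratum"):
            interaction_test(t, lab)

    def test_label_dependent_effect_detected(self):
        # strong benefit only in the labelled subgroup
        c = generate_cohort(
            CohortSpec(n_patients=2500, true_benefit_coefs=(1.5, 0, 0), seed=37)
        )
        lab = (c.truth["latent_skew"] < 0).astype(int).to_numpy()
        assert interaction_test(c.table, lab) < 0.001


class TestPower:
    def test_published_design_gives_096(self):
        p = logrank_power(
            PowerSpec(n_patients=110, n_events=29, allocation=0.5,
                      hazard_ratio=0.25, alpha=0.05)
        )
        assert round(p, 2) == 0.96

    def test_null_hr_limit(self):
        p = logrank_power(PowerSpec(n_patients=10, n_events=10, hazard_ratio=1.0))
        assert p == pytest.approx(0.025, abs=1e-6)

    def test_monotone_in_events_and_effect(self):
        base = dict(n_patients=200, allocation=0.5, alpha=0.05)
        grid = [
            logrank_power(PowerSpec(n_events=d, hazard_ratio=0.5, **base))
            for d in (10, 20, 40, 80)
        ]
        assert grid == sorted(grid) and grid[0] < grid[-1]
        effects = [
            logrank_power(PowerSpec(n_events=30, hazard_ratio=hr, **base))
            for hr in (0.8, 0.6, 0.4, 0.2)
        ]
        assert effects == sorted(effects)

    @pytest.mark.parametrize("subgroup,prev,total", [(110, 0.47, 234), (100, 1.0, 100), (1, 0.5, 2)])
    def test_required_cohort_size(self, subgroup, prev, total):
        assert required_cohort_size(subgroup, prev) == total

    def test_zero_prevalence_rejected(self):
        with pytest.raises(ValueError):
            required_cohort_size(100, 0.0)


class TestRiskStratification:
    @staticmethod
    def row(n_stage, t_stage, vol, pebv):
        return {
            "id": "P", "arm": 0, "time_months": 10.0, "event": 0,
            "n_stage": n_stage, "t_stage": t_stage,
            "tumor_volume_ml": vol, "pebv_dna": pebv,
        }

    def test_factor_counting(self):
        t = pd.DataFrame(
            [self.row(1, 2, 20.0, 500.0), self.row(3, 4, 50.0, 5000.0)]
        )
        counts = count_risk_factors(t)
        assert list(counts) == [0, 4]

    def test_literal_more_than_two_threshold(self):
        t = pd.DataFrame(
            [
                self.row(1, 2, 20.0, 500.0),  # 0 factors
                self.row(2, 2, 40.0, 500.0),  # 2 factors
                self.row(3, 4, 40.0, 500.0),  # 3 factors
                self.row(3, 4, 50.0, 9000.0),  # 4 factors
            ]
        )
        strat = stratify_low_ictos(t)
        assert list(strat.table["risk_group"]) == [
            "low-risk", "low-risk", "high-risk", "high-risk"
        ]

    def test_missing_covariate_excluded_and_counted(self):
        t = pd.DataFrame([self.row(1, 2, 20.0, 500.0), self.row(1, 2, np.nan, 500.0)])
        strat = stratify_low_ictos(t)
        assert strat.n_excluded == 1 and len(strat.table) == 1

    def test_risk_groups_separate_survival(self):
        c = generate_cohort(CohortSpec(n_patients=3000, seed=38))
        strat = stratify_low_ictos(c.table)
        # the generator gives high-risk factors a positive log-hazard, so
        # the high-risk group must show worse survival (HR > 1)
        assert strat.risk_group_comparison is not None
        assert strat.risk_group_comparison.hr > 1.0
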