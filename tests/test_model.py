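import numpy as np
import pandas as pd
import pytest

import ictos
from ictos.cohort import CohortSpec, generate_cohort
from ictos.model import (
    BenefitModel,
    NoSignificantBenefitError,
    backward_select,
    fit_modified_covariate_cox,
    load_published_model,
    redundancy_filter,
    screen_interactions,
)


def latent_cohort(n=1500, coefs=(0.668, 0.442, -0.410), seed=0, **kw):
    """Tabular cohort whose true latent axes serve directly as features."""
    c = generate_cohort(
        CohortSpec(n_patients=n, true_benefit_coefs=coefs, seed=seed, **kw)
    )
    feats = c.truth.set_index("id")[["latent_skew", "latent_hetero", "latent_run"]]
    feats.columns = ["f_skew", "f_hetero", "f_run"]
    return c.table, feats.reset_index(drop=True)


class TestScreen:
    def test_equal_weights_match_unweighted_ranking(self):
        cohort, feats = latent_cohort(n=400, seed=1)
        unweighted = screen_interactions(feats, cohort, None)
        weighted = screen_interactions(feats, cohort, np.full(len(cohort), 2.5))
        assert unweighted.ranking == weighted.ranking
        np.testing.assert_allclose(
            unweighted.table["coef"], weighted.table["coef"], rtol=1e-6
        )

    def test_planted_interaction_outranks_decoys(self):
        rng = np.random.default_rng(2)
        cohort, feats = latent_cohort(n=1200, coefs=(1.0, 0.0, 0.0), seed=2)
        decoys = pd.DataFrame(
            rng.standard_normal((len(cohort), 20)),
            columns=[f"noise_{i}" for i in range(20)],
        )
        table = pd.concat([feats[["f_skew"]], decoys], axis=1)
        result = screen_interactions(table, cohort)
        assert result.ranking[0] == "f_skew"


class TestRedundancyFilter:
    def test_perfectly_correlated_pair_keeps_better_ranked(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(100)
        feats = pd.DataFrame({"a": a, "b": 2.0 * a + 1.0})
        assert redundancy_filter(["a", "b"], feats) == ["a"]

    def test_orthogonal_features_all_retained(self):
        feats = pd.DataFrame(
            {"a": [1.0, 1.0, -1.0, -1.0], "b": [1.0, -1.0, 1.0, -1.0]}
        )
        assert redundancy_filter(["a", "b"], feats) == ["a", "b"]

    def test_greedy_chain_keeps_first_and_last(self):
        # r(A,B) = 0.9, r(B,C) = 0.9, r(A,C) = 0.5, rank A < B < C -> {A, C}
        corr = pd.DataFrame(
            [[1.0, 0.9, 0.5], [0.9, 1.0, 0.9], [0.5, 0.9, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        out = redundancy_filter(["A", "B", "C"], correlations=corr, r_max=0.8)
        assert out == ["A", "C"]

    def test_constant_feature_dropped(self):
        feats = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        assert redundancy_filter(["c", "a"], feats) == ["a"]

    def test_cap_limits_candidates(self):
        rng = np.random.default_rng(5)
        feats = pd.DataFrame(
            rng.standard_normal((50, 8)), columns=list("abcdefgh")
        )
        assert len(redundancy_filter(list("abcdefgh"), feats, max_features=3)) == 3


class TestModifiedCovariate:
    def test_all_zero_covariates_rejected(self):
        cohort, feats = latent_cohort(n=200, seed=6)
        zeros = pd.DataFrame({"z": np.zeros(len(cohort))})
        with pytest.raises(ValueError, match="no informative covariate"):
            fit_modified_covariate_cox(zeros, cohort)

    def test_flipping_treatment_flips_every_gamma(self):
        cohort, feats = latent_cohort(n=800, seed=7)
        fit = fit_modified_covariate_cox(feats, cohort)
        flipped = cohort.assign(arm=1 - cohort["arm"])
        fit_f = fit_modified_covariate_cox(feats, flipped)
        np.testing.assert_allclose(fit.gammas, -fit_f.gammas, rtol=1e-6)

    def test_recovers_planted_interaction_signs(self):
        cohort, feats = latent_cohort(n=2000, seed=8, censor_rate=0.1)
        fit = fit_modified_covariate_cox(feats, cohort)
        assert np.sign(fit.gammas["f_skew"]) == 1.0
        assert np.sign(fit.gammas["f_hetero"]) == 1.0
        assert np.sign(fit.gammas["f_run"]) == -1.0

    def test_no_events_in_an_arm_rejected(self):
        cohort, feats = latent_cohort(n=100, seed=9)
        cohort.loc[cohort["arm"] == 1, "event"] = 0
        with pytest.raises(ValueError, match="no events"):
            fit_modified_covariate_cox(feats, cohort)


class TestBackwardSelect:
    def test_planted_signal_survives_noise_removed(self):
        rng = np.random.default_rng(10)
        cohort, feats = latent_cohort(n=2000, coefs=(1.0, 0.0, 0.0), seed=10)
        feats = feats.assign(
            noise_a=rng.standard_normal(len(cohort)),
            noise_b=rng.standard_normal(len(cohort)),
        )
        model = backward_select(
            ["f_skew", "noise_a", "noise_b"], feats, cohort, alpha=0.05
        )
        assert model.features == ["f_skew"]
        # working gamma positive -> oriented score coefficient negative
        assert model.coefficients["f_skew"] < 0

    def test_all_significant_model_unchanged(self):
        cohort, feats = latent_cohort(
            n=3000, seed=11, censor_rate=0.0, admin_censor_time=1e9
        )
        model = backward_select(list(feats.columns), feats, cohort, alpha=0.05)
        assert set(model.features) == set(feats.columns)

    def test_pure_noise_raises_no_significant(self):
        rng = np.random.default_rng(12)
        cohort, _ = latent_cohort(n=300, coefs=(0.0, 0.0, 0.0), seed=12)
        feats = pd.DataFrame({"n1": rng.standard_normal(300)})
        with pytest.raises(NoSignificantBenefitError):
            backward_select(["n1"], feats, cohort, alpha=1e-6)


class TestScoring:
    def test_published_model_reproduces_printed_example(self):
        model = load_published_model()
        s = model.score(
            {"skewness": -2.02, "GLCM_variance": -1.26, "GLRLM_LRHGLE": 4.58}
        )
        # printed rounded coefficients give 3.78408; the figure legend prints
        # 3.80 from unrounded coefficients
        assert s.value == pytest.approx(3.78408, abs=1e-9)
        assert s.label == "high"

    def test_low_score_example_matches_direct_arithmetic(self):
        model = load_published_model()
        s = model.score(
            {"skewness": 1.82, "GLCM_variance": 1.37, "GLRLM_LRHGLE": -1.46}
        )
        expected = -0.668 * 1.82 - 0.442 * 1.37 + 0.410 * (-1.46)
        assert s.value == pytest.approx(expected, abs=1e-12)
        assert s.label == "low"

    def test_zero_vector_scores_zero_and_low(self):
        model = load_published_model()
        s = model.score({f: 0.0 for f in model.features})
        assert s.value == 0.0 and s.label == "low"

    def test_missing_feature_rejected(self):
        model = load_published_model()
        with pytest.raises(ValueError, match="missing feature"):
            model.score({"skewness": 1.0})

    def test_positive_rescaling_preserves_labels(self):
        model = load_published_model()
        scaled = BenefitModel(
            features=model.features,
            coefficients={k: 3.7 * v for k, v in model.coefficients.items()},
        )
        rng = np.random.default_rng(13)
        table = pd.DataFrame(
            rng.standard_normal((50, 3)), columns=model.features
        )
        a = model.score_table(table)["ictos_group"]
        b = scaled.score_table(table)["ictos_group"]
        assert (a == b).all()

    def test_score_antisymmetric_under_treatment_flip(self):
        cohort, feats = latent_cohort(n=800, seed=14)
        m1 = backward_select(list(feats.columns), feats, cohort, alpha=0.99)
        m2 = backward_select(
            list(feats.columns), feats, cohort.assign(arm=1 - cohort["arm"]),
            alpha=0.99,
        )
        s1 = m1.score_table(feats)["ictos"]
        s2 = m2.score_table(feats)["ictos"]
        np.testing.assert_allclose(s1, -s2, rtol=1e-5, atol=1e-8)


def test_model_yaml_roundtrip(tmp_path):
    model = load_published_model()
    path = tmp_path / "m.yaml"
    model.to_yaml(path)
    back = BenefitModel.from_yaml(path)
    assert back.coefficients == model.coefficients
    assert back.features == model.features
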