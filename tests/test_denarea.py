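"""Conditional logit, AICc multimodel inference, separation, CV."""

import math

import numpy as np
import pandas as pd
import pytest

from denscape import (
    ChoiceDataError,
    ModelFit,
    ModelSpec,
    SelectionTruth,
    SeparationError,
    akaike_weights,
    average_models,
    candidate_models,
    compute_aicc,
    compute_vif,
    condlogit_loglik,
    detect_separation,
    fit_condlogit,
    fit_model_set,
    generate_choice_data,
    kfold_cv,
    split_choice_sets,
    standardize,
    substrate_proportions,
)
from denscape.denarea import standardize_covariates

# AICc column as printed in the published ten-model ranking
PUBLISHED_AICC = [47.48, 48.08, 48.30, 53.95, 54.55, 55.43, 78.04, 81.00, 82.16, 82.71]


def _sets_df(rows):
    return pd.DataFrame(rows, columns=["set_id", "used", "rodent_burrows", "visibility", "shrub_count", "substrate"])


class TestStandardize:
    def test_z_score_hand_example(self):
        z, mean, sd = standardize([1, 2, 3])
        np.testing.assert_allclose(z, [-1, 0, 1])
        assert (mean, sd) == (2.0, 1.0)

    def test_idempotent_on_z_scores(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        z1, _, _ = standardize(x)
        z2, _, _ = standardize(z1)
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ChoiceDataError, match="constant"):
            standardize([5, 5, 5])

    def test_literal_variant(self):
        z, mean, sd = standardize([1.0, 2.0, 3.0], literal=True)
        np.testing.assert_allclose(z, np.array([1, 2, 3]) / (2.0 * 1.0))


class TestVif:
    def test_orthogonal_columns(self):
        df = pd.DataFrame({"a": [-3, -1, 1, 3], "b": [1, -1, -1, 1]})
        vif = compute_vif(df)
        np.testing.assert_allclose(vif, [1.0, 1.0], atol=1e-12)

    def test_correlation_point_nine_closed_form(self):
        x = np.array([-3.0, -1.0, 1.0, 3.0])
        z = np.array([1.0, -1.0, -1.0, 1.0])
        y = 0.9 * x / np.linalg.norm(x) + math.sqrt(0.19) * z / np.linalg.norm(z)
        vif = compute_vif(pd.DataFrame({"x": x, "y": y}))
        np.testing.assert_allclose(vif, 1 / (1 - 0.81), atol=1e-9)

    def test_duplicated_column_infinite(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 4.0, 3.0]})
        df["b"] = df["a"]
        df["c"] = [0.0, 1.0, 0.5, 2.0]
        vif = compute_vif(df)
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])


class TestModelSpec:
    def test_interaction_requires_mains(self):
        with pytest.raises(ChoiceDataError, match="main effects"):
            ModelSpec(("rodent_burrows", "rodent_burrows:visibility"))

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ChoiceDataError):
            ModelSpec(("elevation",))

    def test_candidate_set_mirrors_published_designs(self):
        specs = candidate_models()
        assert len(specs) == 10
        assert specs[0].name == "rodent_burrows + visibility"
        assert all(s.k <= 3 for s in specs)


def _loglik_enumeration(beta, df, terms):
    """Symbolic brute force: plain-python row loop, no shared code paths."""
    total = 0.0
    for _, grp in df.groupby("set_id"):
        utils = []
        used_u = None
        for _, row in grp.iterrows():
            u = 0.0
            for b, t in zip(beta, terms):
                v = 1.0
                for part in t.split(":"):
                    v *= float(row[part])
                u += b * v
            utils.append(u)
            if row["used"] == 1:
                used_u = u
        total += used_u - math.log(sum(math.exp(u) for u in utils))
    return total


class TestCondlogitLoglik:
    def test_uniform_choice_closed_form(self):
        df = generate_choice_data(26, 4, SelectionTruth(), seed=3)
        ll = condlogit_loglik([0.0], df, ("rodent_burrows",))
        assert ll == pytest.approx(-26 * math.log(5), abs=1e-12)

    def test_dominating_used_row_approaches_zero(self):
        rows = [(0, 1, 20.0, 0, 0, "other"), (0, 0, 0.0, 0, 0, "other")]
        df = _sets_df(rows)
        ll = condlogit_loglik([1.0], df, ("rodent_burrows",))
        assert -1e-6 < ll < 0

    def test_matches_symbolic_enumeration(self):
        df = generate_choice_data(7, 3, SelectionTruth(choice_betas={"visibility": 0.2}), seed=4)
        terms = ("rodent_burrows", "visibility", "rodent_burrows:visibility")
        beta = [0.3, -0.2, 0.05]
        ll = condlogit_loglik(beta, df, terms)
        assert ll == pytest.approx(_loglik_enumeration(beta, df, terms), abs=1e-12)

    def test_non_finite_beta_rejected(self):
        df = generate_choice_data(3, 2, SelectionTruth(), seed=5)
        with pytest.raises(ChoiceDataError):
            condlogit_loglik([float("nan")], df, ("visibility",))

    def test_malformed_sets_rejected(self):
        df = _sets_df([(0, 1, 1, 1, 1, "other"), (0, 1, 2, 2, 2, "other")])
        with pytest.raises(ChoiceDataError, match="used rows"):
            split_choice_sets(df)


class TestFitCondlogit:
    def test_tiny_instance_matches_grid_search(self):
        df = generate_choice_data(3, 3, SelectionTruth(choice_betas={"rodent_burrows": 0.7}), seed=6)
        fit = fit_condlogit(ModelSpec(("rodent_burrows",)), df)
        grid = np.arange(-5.0, 5.0, 1e-4)
        from denscape.denarea import _GroupedDesign, _loglik

        gd = _GroupedDesign(df, ("rodent_burrows",))
        lls = np.array([_loglik(np.array([b]), gd) for b in grid])
        assert abs(fit.beta["rodent_burrows"] - grid[np.argmax(lls)]) <= 1e-4

    def test_matches_statsmodels_conditional_logit(self, choice_df):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        std, _ = standardize_covariates(choice_df)
        terms = ("rodent_burrows", "visibility")
        fit = fit_condlogit(ModelSpec(terms), std)
        sm = ConditionalLogit(
            std["used"].to_numpy(),
            std[list(terms)].to_numpy(),
            groups=std["set_id"].to_numpy(),
        ).fit(disp=0)
        ours = np.array([fit.beta[t] for t in terms])
        np.testing.assert_allclose(ours, sm.params, atol=2e-3)
        np.testing.assert_allclose([fit.se[t] for t in terms], sm.bse, atol=2e-3)
        # our optimum is at least as good as the cross-check's
        assert fit.loglik >= sm.llf - 1e-6

    def test_optimum_unimproved_by_random_perturbations(self, choice_df):
        from denscape.denarea import _GroupedDesign, _loglik

        std, _ = standardize_covariates(choice_df)
        terms = ("rodent_burrows", "visibility")
        fit = fit_condlogit(ModelSpec(terms), std)
        gd = _GroupedDesign(std, terms)
        beta_hat = np.array([fit.beta[t] for t in terms])
        ll_hat = _loglik(beta_hat, gd)
        rng = np.random.default_rng(11)
        for scale in (1e-3, 1e-2, 0.1, 1.0):
            pert = rng.normal(scale=scale, size=(2500, 2))
            assert all(_loglik(beta_hat + p, gd) <= ll_hat + 1e-12 for p in pert)

    def test_complete_separation_raises_with_direction_to_detector(self):
        rows = []
        for s in range(12):
            rows.append((s, 1, 10.0, 1.0, 0, "other"))
            rows.append((s, 0, 0.0, 1.0, 0, "other"))
        df = _sets_df(rows)
        with pytest.raises(SeparationError, match="detect_separation"):
            fit_condlogit(ModelSpec(("rodent_burrows",)), df)


class TestAicc:
    def test_direct_formula_evaluation(self):
        assert compute_aicc(-20, 3, 26) == pytest.approx(40 + 6 + 24 / 22, abs=1e-12)

    def test_zero_parameters_reduces_to_deviance(self):
        assert compute_aicc(-13.5, 0, 26) == 27.0

    def test_matches_plain_aic_asymptotically(self):
        aic = -2 * (-100.0) + 2 * 3
        assert compute_aicc(-100.0, 3, 10**8) == pytest.approx(aic, abs=1e-6)

    def test_small_sample_guard(self):
        with pytest.raises(ChoiceDataError):
            compute_aicc(-10, 5, 6)


class TestAkaikeWeights:
    def test_published_aicc_column_reproduces_deltas_and_weights(self):
        delta, w = akaike_weights(PUBLISHED_AICC)
        assert delta[3] == pytest.approx(6.47, abs=1e-9)
        assert tuple(np.round(w[:3], 2)) == (0.40, 0.30, 0.27)

    def test_equal_values_split_evenly(self):
        _, w = akaike_weights([100.0, 100.0])
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_shift_invariance_and_normalization(self):
        d1, w1 = akaike_weights(PUBLISHED_AICC)
        d2, w2 = akaike_weights([a + 123.4 for a in PUBLISHED_AICC])
        np.testing.assert_allclose(w1, w2, atol=1e-12)
        np.testing.assert_allclose(d1, d2, atol=1e-10)
        assert w1.sum() == pytest.approx(1.0, abs=1e-12)


def _fit(terms, betas, ses, weight, delta):
    spec = ModelSpec(terms)
    return ModelFit(
        spec=spec,
        beta=dict(zip(terms, betas)),
        se=dict(zip(terms, ses)),
        loglik=0.0,
        k=len(terms),
        n_sets=26,
        converged=True,
        aicc=0.0,
        delta_aicc=delta,
        weight=weight,
    )


class TestAverageModels:
    def test_single_model_is_identity(self):
        f = _fit(("rodent_burrows",), [1.7], [0.4], 1.0, 0.0)
        out = average_models([f]).set_index("term")
        assert out.loc["rodent_burrows", "wt_beta"] == pytest.approx(1.7)
        assert out.loc["rodent_burrows", "un_se"] == pytest.approx(0.4)

    def test_published_coefficients_exponentiate_to_published_odds(self):
        # averaged coefficients 0.06 (shrub) and 0.07 (interaction) ->
        # odds ratios 1.06 and 1.07 at 2 dp
        f = _fit(
            ("rodent_burrows", "visibility", "shrub_count", "rodent_burrows:visibility"),
            [2.09, 1.40, 0.06, 0.07],
            [0.57, 0.65, 0.09, 0.13],
            1.0,
            0.0,
        )
        out = average_models([f]).set_index("term")
        assert round(out.loc["shrub_count", "odds_ratio"], 2) == 1.06
        assert round(out.loc["rodent_burrows:visibility", "odds_ratio"], 2) == 1.07
        assert round(out.loc["rodent_burrows", "odds_ratio"], 2) == 8.08  # exp(2.09)

    def test_natural_vs_zero_substitution_modes(self):
        f1 = _fit(("rodent_burrows", "visibility"), [2.0, 1.0], [0.5, 0.5], 0.6, 0.0)
        f2 = _fit(("rodent_burrows",), [1.5], [0.4], 0.4, 1.0)
        nat = average_models([f1, f2]).set_index("term")
        # visibility appears only in f1: natural averaging returns its value
        assert nat.loc["visibility", "wt_beta"] == pytest.approx(1.0)
        zs = average_models([f1, f2], zero_substitution=True).set_index("term")
        assert zs.loc["visibility", "wt_beta"] == pytest.approx(0.6 * 1.0)

    def test_unconditional_se_includes_between_model_variance(self):
        f1 = _fit(("rodent_burrows",), [2.0], [0.5], 0.5, 0.0)
        f2 = _fit(("rodent_burrows",), [1.0], [0.5], 0.5, 1.0)
        out = average_models([f1, f2]).set_index("term")
        expected = 0.5 * math.sqrt(0.25 + 0.25) + 0.5 * math.sqrt(0.25 + 0.25)
        assert out.loc["rodent_burrows", "un_se"] == pytest.approx(expected)
        assert out.loc["rodent_burrows", "un_se"] > 0.5

    def test_empty_confidence_set_rejected(self):
        f = _fit(("rodent_burrows",), [1.0], [0.2], 1.0, 9.0)
        with pytest.raises(ChoiceDataError):
            average_models([f], delta_threshold=4.0)

    def test_odds_ratio_within_its_ci(self):
        f = _fit(("rodent_burrows",), [2.09], [0.57], 1.0, 0.0)
        out = average_models([f]).iloc[0]
        assert out["lo"] <= out["odds_ratio"] <= out["hi"]


class TestDetectSeparation:
    @staticmethod
    def _fig3_like():
        rows = []
        sid = 0
        used_counts = [("earthen_bund", 18), ("boulder_pile", 7), ("other", 1)]
        avail = ["earthen_bund"] * 5 + ["boulder_pile"] * 3 + ["other"] * 96
        i = 0
        for sub, cnt in used_counts:
            for _ in range(cnt):
                rows.append((sid, 1, 0, 0, 0, sub))
                for _ in range(4):
                    rows.append((sid, 0, 0, 0, 0, avail[i % 104]))
                    i += 1
                sid += 1
        return _sets_df(rows)

    def test_complete_separation_flagged(self):
        rows = []
        for s in range(10):
            rows.append((s, 1, 0, 0, 0, "earthen_bund"))
            rows += [(s, 0, 0, 0, 0, "other")] * 4
        rep = detect_separation(_sets_df(rows), "substrate")
        assert rep.flag == "complete"

    def test_study_pattern_is_quasi_complete(self):
        rep = detect_separation(self._fig3_like(), "substrate")
        assert rep.flag == "quasi"
        assert rep.sensitivity >= 0.9 and rep.specificity >= 0.9

    def test_balanced_substrate_not_flagged(self):
        rng = np.random.default_rng(2)
        rows = []
        for s in range(40):
            subs = rng.choice(["earthen_bund", "boulder_pile", "other"], 5)
            for j in range(5):
                rows.append((s, int(j == 0), 0, 0, 0, subs[j]))
        rep = detect_separation(_sets_df(rows), "substrate")
        assert rep.flag == "none"

    def test_continuous_threshold_detection(self):
        rows = []
        for s in range(15):
            rows.append((s, 1, 9.0 + s % 3, 0, 0, "other"))
            rows += [(s, 0, float(s % 4), 0, 0, "other")] * 4
        rep = detect_separation(_sets_df(rows), "rodent_burrows")
        assert rep.flag == "complete"


class TestKfoldCv:
    def test_perfectly_separable_data_gives_zero_error(self):
        rows = []
        for s in range(20):
            rows.append((s, 1, 10.0, 0, 0, "other"))
            rows += [(s, 0, float(s % 3), 0, 0, "other")] * 4
        df = _sets_df(rows)
        assert kfold_cv(ModelSpec(("rodent_burrows",)), df, k=5, seed=1) == 0.0

    def test_invalid_fold_counts_rejected(self, choice_df):
        with pytest.raises(ChoiceDataError):
            kfold_cv(ModelSpec(("rodent_burrows",)), choice_df, k=1, seed=0)
        with pytest.raises(ChoiceDataError):
            kfold_cv(ModelSpec(("rodent_burrows",)), choice_df, k=10_000, seed=0)

    def test_leave_one_out_allowed(self, choice_df):
        sub = choice_df[choice_df["set_id"] < 20]
        delta = kfold_cv(ModelSpec(("rodent_burrows",)), sub, k=20, seed=3)
        assert 0.0 <= delta <= 1.0

    def test_informative_model_beats_chance(self, choice_df):
        std, _ = standardize_covariates(choice_df)
        delta = kfold_cv(ModelSpec(("rodent_burrows", "visibility")), std, k=10, seed=4)
        assert delta < 0.5  # chance level is 0.8 with 4 available per set


class TestModelSetAndPipelinePieces:
    def test_fit_model_set_orders_and_normalizes(self, choice_df):
        std, _ = standardize_covariates(choice_df)
        fits = fit_model_set(candidate_models(), std)
        aiccs = [f.aicc for f in fits]
        assert aiccs == sorted(aiccs)
        assert fits[0].delta_aicc == 0.0
        assert sum(f.weight for f in fits) == pytest.approx(1.0, abs=1e-12)

    def test_k_offset_shifts_parameter_count(self, choice_df):
        std, _ = standardize_covariates(choice_df)
        k0 = {f.spec.name: f.k for f in fit_model_set(candidate_models(), std, k_offset=0)}
        k1 = {f.spec.name: f.k for f in fit_model_set(candidate_models(), std, k_offset=1)}
        assert all(k1[name] == k + 1 for name, k in k0.items())

    def test_true_model_wins_on_informative_data(self, choice_df):
        std, _ = standardize_covariates(choice_df)
        fits = fit_model_set(candidate_models(), std)
        assert "rodent_burrows" in fits[0].spec.terms
        assert "visibility" in fits[0].spec.terms


class TestSubstrateProportions:
    def test_study_used_composition(self):
        df = TestDetectSeparation._fig3_like()
        out = substrate_proportions(df)
        used = out[out["group"] == "used"].set_index("category")["proportion"]
        assert round(used["earthen_bund"], 2) == 0.69
        assert round(used["boulder_pile"], 2) == 0.27
        assert round(used["other"], 2) == 0.04
        avail = out[out["group"] == "available"].set_index("category")["proportion"]
        assert round(avail["other"], 2) == 0.92

    def test_single_category(self):
        rows = [(0, 1, 0, 0, 0, "earthen_bund"), (0, 0, 0, 0, 0, "earthen_bund")]
        out = substrate_proportions(_sets_df(rows))
        assert (out["proportion"] == 1.0).all()

    def test_proportions_sum_to_one(self, choice_df):
        out = substrate_proportions(choice_df)
        for _, grp in out.groupby("group"):
            assert grp["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
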