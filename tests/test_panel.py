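"""Panel assembly, random-intercept models, Kruskal-Wallis and Dunn tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from palmwatch.panel import (
    _design_matrix,
    build_panel,
    dunn_posthoc,
    fit_random_effects,
    kruskal_wallis,
)
from palmwatch.synthetic import DEFAULT_PRICES, PanelSpec, generate_panel, table2_year_effects


def _split_panel(panel):
    """Decompose a generated panel into build_panel's input tables."""
    coverage = panel[["plantation_id", "year", "coverage"]].copy()
    indices = panel[["plantation_id", "year", "ndvi", "ndmi", "bsi"]].copy()
    plantations = (
        panel.groupby("plantation_id")
        .first()
        .reset_index()[["plantation_id", "mill", "type", "cohort"]]
    )
    plantations["certification_year"] = (
        plantations["cohort"].str.slice(-4).astype(int)
    )
    return coverage, indices, plantations.drop(columns="cohort")


class TestBuildPanel:
    def test_48_plantations_7_years_gives_336_rows(self):
        raw, _ = generate_panel(PanelSpec(n_plantations=48, share_certified_2018=1.0, seed=1))
        coverage, indices, plantations = _split_panel(raw)
        panel = build_panel(coverage, indices, plantations, DEFAULT_PRICES)
        cohort = panel[panel["cohort"] == "certified-2018"]
        assert len(cohort) == 336

    def test_empty_coverage_gives_empty_panel(self):
        panel = build_panel(pd.DataFrame(), pd.DataFrame(), pd.DataFrame(), DEFAULT_PRICES)
        assert panel.empty

    def test_duplicate_plantation_year_raises(self):
        raw, _ = generate_panel(PanelSpec(n_plantations=4, seed=2))
        coverage, indices, plantations = _split_panel(raw)
        coverage = pd.concat([coverage, coverage.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            build_panel(coverage, indices, plantations, DEFAULT_PRICES)

    def test_missing_price_year_raises(self):
        raw, _ = generate_panel(PanelSpec(n_plantations=4, seed=2))
        coverage, indices, plantations = _split_panel(raw)
        prices = {y: p for y, p in DEFAULT_PRICES.items() if y != 2020}
        with pytest.raises(ValueError, match="2020"):
            build_panel(coverage, indices, plantations, prices)

    def test_missing_coverage_rows_dropped(self):
        raw, _ = generate_panel(PanelSpec(n_plantations=4, seed=2))
        coverage, indices, plantations = _split_panel(raw)
        coverage.loc[coverage.index[:3], "coverage"] = np.nan
        panel = build_panel(coverage, indices, plantations, DEFAULT_PRICES)
        assert len(panel) == len(coverage) - 3

    def test_type_dummies_use_small_grower_baseline(self):
        raw, _ = generate_panel(PanelSpec(n_plantations=30, seed=4))
        coverage, indices, plantations = _split_panel(raw)
        panel = build_panel(coverage, indices, plantations, DEFAULT_PRICES)
        sg = panel[panel["type"] == "small_grower"]
        assert (sg["self_produced"] == 0).all() and (sg["outsourced"] == 0).all()
        assert ((panel["self_produced"] + panel["outsourced"]) <= 1).all()


class TestFitRandomEffects:
    def test_wald_intervals_cover_truth(self):
        """95% Wald intervals cover each true coefficient in most replicates."""
        terms = ["self_produced", "outsourced", "ndvi", "ndmi", "bsi", "price",
                 "year_2019", "year_2021", "year_2022"]
        covered = {t: 0 for t in terms}
        n_rep = 40
        for rep in range(n_rep):
            spec = PanelSpec(
                n_plantations=96, seed=20_000 + rep, true_betas=table2_year_effects()
            )
            panel, truth = generate_panel(spec)
            fit = fit_random_effects(panel)
            for t in terms:
                lo = fit.coefficients[t] - 1.96 * fit.std_errors[t]
                hi = fit.coefficients[t] + 1.96 * fit.std_errors[t]
                covered[t] += lo <= truth["betas"].get(t, 0.0) <= hi
        for t, n_cov in covered.items():
            assert n_cov / n_rep >= 0.85, (t, n_cov)

    def test_zero_random_intercept_matches_pooled_ols(self):
        panel, _ = generate_panel(
            PanelSpec(n_plantations=48, random_intercept_sd=0.0, seed=5)
        )
        fit = fit_random_effects(panel)
        X, names, _ = _design_matrix(panel, True, 2018)
        ols = sm.OLS(panel["coverage"].to_numpy(), X).fit()
        assert fit.random_intercept_var < 1e-4
        got = np.array([fit.coefficients[n] for n in names])
        np.testing.assert_allclose(got, ols.params, atol=1e-6)

    def test_conditional_r2_at_least_marginal(self):
        panel, _ = generate_panel(PanelSpec(n_plantations=30, seed=6))
        fit = fit_random_effects(panel)
        assert fit.conditional_r2 >= fit.marginal_r2
        assert 0.0 <= fit.marginal_r2 <= 1.0

    def test_information_criteria_consistent_with_loglik(self):
        panel, _ = generate_panel(PanelSpec(n_plantations=30, seed=7))
        fit = fit_random_effects(panel)
        k = len(fit.coefficients) + 2
        assert abs(fit.aic - (2 * k - 2 * fit.log_likelihood)) < 1e-8
        assert abs(fit.bic - (k * np.log(fit.n_obs) - 2 * fit.log_likelihood)) < 1e-8

    def test_aliased_final_year_dummy_dropped(self):
        panel, _ = generate_panel(PanelSpec(n_plantations=20, seed=8))
        fit = fit_random_effects(panel)
        assert "year_2023" not in fit.coefficients
        assert fit.extra["dropped_aliased_terms"] == ["year_2023"]
        assert fit.n_obs == len(panel)

    def test_too_few_groups_or_years_raises(self):
        panel, _ = generate_panel(PanelSpec(n_plantations=20, seed=9))
        one_plant = panel[panel["plantation_id"] == "P000"]
        with pytest.raises(ValueError, match="plantations"):
            fit_random_effects(one_plant)
        one_year = panel[panel["year"] == 2018]
        with pytest.raises(ValueError, match="years"):
            fit_random_effects(one_year)

    def test_duplicated_regressor_is_rejected(self):
        panel, _ = generate_panel(PanelSpec(n_plantations=20, seed=10))
        panel = panel.copy()
        panel["ndmi"] = panel["ndvi"] * 2.0  # exact collinearity
        with pytest.raises(ValueError, match="singular"):
            fit_random_effects(panel)

    def test_summary_table_mentions_fit_statistics(self):
        panel, _ = generate_panel(PanelSpec(n_plantations=20, seed=11))
        text = fit_random_effects(panel).summary_table()
        for needle in ("Marginal R2", "Conditional R2", "Log likelihood",
                       "Akaike", "Bayesian", "Observations"):
            assert needle in text


class TestKruskalWallis:
    def test_three_groups_df_two_and_hand_value(self):
        h, df, p = kruskal_wallis([np.array([1, 4]), np.array([2, 5]), np.array([3, 6])])
        assert df == 2
        # hand computation: rank sums 5, 7, 9 -> H = 12/42 * 155/2 - 21 = 8/7
        assert h == pytest.approx(8 / 7)

    def test_matches_brute_force_permutation_oracle(self):
        groups = [np.array([1, 4]), np.array([2, 5]), np.array([3, 6])]
        h_obs, _, p_chi2 = kruskal_wallis(groups)

        def h_stat(assignment, values):
            n = len(values)
            ranks = np.argsort(np.argsort(values)) + 1
            total = 0.0
            for g in range(3):
                r = ranks[np.array(assignment) == g]
                total += r.sum() ** 2 / len(r)
            return 12 / (n * (n + 1)) * total - 3 * (n + 1)

        values = np.array([1, 4, 2, 5, 3, 6])
        labels = [0, 0, 1, 1, 2, 2]
        assert h_stat(labels, values) == pytest.approx(h_obs)
        # exact permutation null over every relabeling
        count = sum(
            h_stat(perm, values) >= h_obs - 1e-12
            for perm in set(itertools.permutations(labels))
        )
        p_exact = count / len(set(itertools.permutations(labels)))
        assert 0.0 < p_exact < 1.0
        assert abs(p_chi2 - p_exact) < 0.25  # chi2 approximation at n=6

    def test_interleaved_identical_groups_give_null_result(self):
        a = np.array([1.0, 3.0, 5.0, 7.0, 9.0, 11.0])
        b = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        h, _, p = kruskal_wallis([a, b])
        assert h < 0.5
        assert p > 0.5

    def test_two_groups_equal_rank_sum_chi2_form(self):
        # oracle: for k=2, H equals the normalized squared rank-sum deviation
        a, b = np.array([3.0, 9.0, 1.0]), np.array([7.0, 5.0, 11.0, 13.0])
        h, _, _ = kruskal_wallis([a, b])
        pooled = np.concatenate([a, b])
        n = len(pooled)
        ranks = np.argsort(np.argsort(pooled)) + 1
        r1 = ranks[: len(a)].sum()
        expect = len(a) * (n + 1) / 2
        var = len(a) * len(b) * (n + 1) / 12
        assert h == pytest.approx((r1 - expect) ** 2 / var)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis([np.array([1.0]), np.array([])])
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_wallis([np.array([1.0, 2.0])])


class TestDunnPosthoc:
    def test_hand_computed_untied_example(self):
        # N=9, no ties: mean ranks 2, 5, 8; SE = sqrt(7.5 * 2/3) = sqrt(5)
        out = dunn_posthoc(
            [np.array([1, 2, 3]), np.array([4, 5, 6]), np.array([7, 8, 9])],
            labels=["A", "B", "C"],
        )
        by_pair = {(r["group_a"], r["group_b"]): r for r in out.to_dict("records")}
        assert by_pair[("A", "B")]["z"] == pytest.approx(-3 / np.sqrt(5))
        assert by_pair[("A", "C")]["z"] == pytest.approx(-6 / np.sqrt(5))
        assert by_pair[("A", "B")]["p"] == pytest.approx(0.17971, abs=1e-4)

    def test_hand_computed_tie_correction(self):
        # pooled 1,2,2,2,3,4: tie group of 3 -> T=24,
        # var_base = 6*7/12 - 24/60 = 3.1; mean ranks 7/3 and 14/3
        out = dunn_posthoc([np.array([1, 2, 2]), np.array([2, 3, 4])])
        z = out["z"].iloc[0]
        assert z == pytest.approx((7 / 3 - 14 / 3) / np.sqrt(3.1 * (2 / 3)))
        assert z == pytest.approx(-1.62309, abs=1e-4)

    def test_sign_convention_and_antisymmetry(self):
        rng = np.random.default_rng(0)
        low = rng.normal(0.0, 1.0, 30)
        high = rng.normal(5.0, 1.0, 30)
        fwd = dunn_posthoc([high, low])
        rev = dunn_posthoc([low, high])
        assert fwd["z"].iloc[0] > 0  # first group larger => positive z
        assert fwd["z"].iloc[0] == pytest.approx(-rev["z"].iloc[0])
        assert fwd["p"].iloc[0] == pytest.approx(rev["p"].iloc[0])

    def test_holm_adjustment_is_monotone(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1.0, 15) for m in (0.0, 0.5, 2.0)]
        out = dunn_posthoc(groups, adjust="holm")
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()

    def test_fewer_than_two_groups_raises(self):
        with pytest.raises(ValueError, match="2 groups"):
            dunn_posthoc([np.array([1.0, 2.0])])
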