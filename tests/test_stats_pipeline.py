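import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from egoprl.stats_pipeline import (
    backward_stepwise,
    bayes_factor_two_sample,
    elbow_kmeans,
    fit_ols_terms,
    fit_reduced_model_mu30,
    fit_reduced_model_psych,
    mean_split,
    paranoia_group,
    pca_scores,
    psychopathology_composite,
    score_covid,
    score_general,
    spearman,
    wilcoxon_rank_sum,
)

from _oracles import aic_of_subset, backward_reachable_subsets, oracle_jzs_bf10


class TestScoring:
    @pytest.mark.parametrize("score,expected", [(11, "high"), (10, "low"),
                                                (0, "low"), (40, "high")])
    def test_clinical_cutoff(self, score, expected):
        assert paranoia_group(score) == expected

    def test_general_score_bounds_and_sum(self):
        assert score_general([1, 1, 1, 1, 1]) == 5
        assert score_general([5, 5, 5, 5, 5]) == 25
        assert score_general([2, 4, 3, 1, 5]) == 15
        with pytest.raises(ValueError):
            score_general([0, 1, 1, 1, 1])

    def test_covid_score(self):
        assert score_covid([7, 7, 7, 7, 7]) == 35
        assert score_covid([1, 2, 3, 4, 5]) == 15

    def test_composite_of_means_is_zero(self):
        rng = np.random.default_rng(0)
        bai, bdi, par = rng.normal(10, 3, 50), rng.normal(12, 4, 50), rng.normal(20, 6, 50)
        comp = psychopathology_composite(bai, bdi, par)
        assert comp.mean() == pytest.approx(0.0, abs=1e-12)
        hand = (stats.zscore(bai) + stats.zscore(bdi) + stats.zscore(par)) / 3
        np.testing.assert_allclose(comp, hand, rtol=1e-12)

    def test_composite_one_sd_above_on_all_three(self):
        """An ego one population-SD above the mean on every instrument has a
        composite of exactly 1."""
        bai = np.array([8.0, 10.0, 12.0, 10.0, 10.0 + math.sqrt(2)])
        bdi = 2 * bai
        par = bai + 5
        comp = psychopathology_composite(bai, bdi, par)
        z_last = (bai[-1] - bai.mean()) / bai.std()
        assert comp[-1] == pytest.approx(z_last)

    def test_mean_split_tie_rule(self):
        assert list(mean_split([1, 2, 3, 4])) == ["low", "low", "high", "high"]
        assert list(mean_split([5, 5, 5])) == ["low"] * 3


class TestClustering:
    def test_planted_three_clusters_selected_and_recovered(self):
        rng = np.random.default_rng(1)
        centers = rng.normal(0, 8, size=(3, 7))
        X = np.vstack([c + rng.normal(0, 1, size=(60, 7)) for c in centers])
        truth = np.repeat([0, 1, 2], 60)
        k_star, labels, wcss = elbow_kmeans(stats.zscore(X, axis=0), seed=0)
        assert k_star == 3
        assert adjusted_rand_score(truth, labels) > 0.95
        assert (np.diff(wcss.values) <= 1e-9).all()  # WCSS nonincreasing in k

    def test_duplicated_point_degenerate(self):
        X = np.tile([1.0, 2.0, 3.0], (20, 1))
        k_star, labels, wcss = elbow_kmeans(X, k_range=range(1, 5), seed=0)
        assert k_star == 1
        assert wcss.iloc[0] == pytest.approx(0.0)

    def test_pca_one_dimensional_data(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=100)
        direction = rng.normal(size=7)
        X = np.outer(t, direction)
        loadings, scores, evr = pca_scores(X, standardize=False)
        assert evr[0] == pytest.approx(1.0)
        # components orthonormal
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(7), atol=1e-9)

    def test_pca_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 5))
        _, _, evr = pca_scores(X, standardize=True)
        Xz = stats.zscore(X, axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Xz.T)))[::-1]
        np.testing.assert_allclose(evr, eig / eig.sum(), rtol=1e-8)
        assert (np.diff(evr) <= 1e-12).all()


def _toy_data(seed=4, n=200, beta=(1.5, 0.0, 0.0)):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({c: rng.normal(size=n) for c in "ABC"})
    df["y"] = sum(b * df[c] for b, c in zip(beta, "ABC")) + rng.normal(size=n)
    return df


class TestStepwise:
    def test_true_predictor_retained_noise_dropped(self):
        hits = 0
        for seed in range(20):
            df = _toy_data(seed=seed)
            fit = backward_stepwise(df, "y", [("A",), ("B",), ("C",)])
            if ("A",) in fit.terms:
                hits += 1
        assert hits == 20

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exhaustive_backward_reachable_search(self, seed):
        """Greedy elimination lands on the AIC-best subset among all subsets
        reachable by marginality-respecting removals (toy 5-term design)."""
        rng = np.random.default_rng(seed)
        n = 150
        df = pd.DataFrame({"A": rng.normal(size=n), "B": rng.normal(size=n)})
        df["y"] = (1.2 * df["A"] - 0.8 * df["A"] * df["B"]
                   + rng.normal(size=n))
        terms = [("A",), ("B",), ("A", "B")]
        fit = backward_stepwise(df, "y", terms)

        cols = {"A": df["A"], "B": df["B"], "A:B": df["A"] * df["B"]}
        name = {("A",): "A", ("B",): "B", ("A", "B"): "A:B"}
        best = None
        for subset in backward_reachable_subsets(terms):
            aic = aic_of_subset(cols, df["y"], [name[t] for t in subset])
            if best is None or aic < best[0]:
                best = (aic, set(subset))
        assert set(fit.terms) == best[1]
        assert fit.aic == pytest.approx(best[0], rel=1e-9)

    def test_marginality_never_violated(self):
        df = _toy_data(seed=9)
        df["y"] = df["y"] + 0.0 * df["A"]
        terms = [("A",), ("B",), ("C",), ("A", "B"), ("B", "C")]
        fit = backward_stepwise(df, "y", terms)
        for t in fit.terms:
            if len(t) > 1:
                for f in t:
                    assert (f,) in fit.terms

    def test_optimal_full_model_returned_unchanged(self):
        rng = np.random.default_rng(10)
        n = 400
        df = pd.DataFrame({"A": rng.normal(size=n), "B": rng.normal(size=n)})
        df["y"] = 2 * df["A"] + 2 * df["B"] + 3 * df["A"] * df["B"] + rng.normal(size=n)
        terms = [("A",), ("B",), ("A", "B")]
        fit = backward_stepwise(df, "y", terms)
        assert set(fit.terms) == set(terms)

    def test_rank_deficient_design_named(self):
        df = _toy_data(seed=11)
        df["D"] = df["A"]
        with pytest.raises(ValueError, match="collinear"):
            fit_ols_terms(df, "y", [("A",), ("D",)])


class TestReducedModels:
    def test_exact_recovery_with_zero_noise(self):
        rng = np.random.default_rng(12)
        n = 100
        df = pd.DataFrame({c: rng.normal(size=n)
                           for c in ("SIZE", "TIES", "KIN", "BELIEF")})
        df["psychopathology"] = (0.5 - 0.3 * df["SIZE"] + 0.2 * df["TIES"]
                                 - 0.4 * df["SIZE"] * df["BELIEF"])
        fit = fit_reduced_model_psych(df)
        assert fit.coef(("SIZE", "BELIEF")) == pytest.approx(-0.4)
        assert fit.coef(("SIZE",)) == pytest.approx(-0.3)
        assert fit.rsquared == pytest.approx(1.0)
        assert fit.df_model == 7

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({c: rng.normal(size=6)
                           for c in ("SIZE", "TIES", "KIN", "BELIEF")})
        df["psychopathology"] = rng.normal(size=6)
        with pytest.raises(ValueError, match="observations"):
            fit_reduced_model_psych(df)

    def test_mu30_model_three_way_recovery(self):
        rng = np.random.default_rng(14)
        n = 3000
        df = pd.DataFrame({c: rng.normal(size=n)
                           for c in ("PARANOIA", "SIZE", "TIES", "KIN", "BELIEF")})
        df["mu30"] = (-3.0 + 0.2 * df["PARANOIA"]
                      - 0.25 * df["PARANOIA"] * df["TIES"] * df["BELIEF"]
                      + 0.5 * rng.normal(size=n))
        fit = fit_reduced_model_mu30(df)
        assert fit.coef(("PARANOIA", "TIES", "BELIEF")) == pytest.approx(-0.25, abs=0.05)
        assert fit.df_model == 13


class TestSimpleStats:
    def test_wilcoxon_matches_exact_permutation_oracle(self):
        """Small-sample two-sided p against scipy's exact enumeration."""
        x, y = [1.2, 3.4, 2.2, 5.0], [0.1, 0.4, 2.1]
        res = wilcoxon_rank_sum(x, y)
        exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.statistic == exact.statistic
        assert res.p_value == pytest.approx(exact.pvalue, abs=0.03)

    def test_spearman_perfect_monotone(self):
        res = spearman([1, 2, 3, 4], [10, 100, 1000, 10000])
        assert res.statistic == pytest.approx(1.0)

    def test_spearman_ties_midranked(self):
        res = spearman([1, 2, 2, 3], [1, 2, 3, 4])
        rho, _ = stats.spearmanr([1, 2, 2, 3], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(rho)

    def test_bf10_matches_quadrature_oracle(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0.0, 1, 40)
        y = rng.normal(0.6, 1, 35)
        assert bayes_factor_two_sample(x, y) == pytest.approx(
            oracle_jzs_bf10(x, y), rel=1e-3)

    def test_bf10_direction(self):
        rng = np.random.default_rng(16)
        null_x, null_y = rng.normal(0, 1, 400), rng.normal(0, 1, 400)
        assert bayes_factor_two_sample(null_x, null_y) < 1
        eff_x, eff_y = rng.normal(0, 1, 400), rng.normal(1.0, 1, 400)
        assert bayes_factor_two_sample(eff_x, eff_y) > 1
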