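"""Discretization, elastic-net LOSO-CV, evaluation metrics, leakage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fcdstrat.stratify import (AgeSexCorrector, ModelSpec, add_genetic_feature,
                               auc_score, discretize, fit_elasticnet_logistic,
                               loso_cv, permutation_pvalue, pooled_spearman,
                               robust_sd, site_avg_auc)


class TestRobustSd:
    def test_standard_normal_gives_one(self):
        # quantile grid of the standard normal: IQR = 2 * 0.67449
        v = sps.norm.ppf((np.arange(100000) + 0.5) / 100000)
        assert robust_sd(v) == pytest.approx(1.0, abs=0.01)

    def test_one_to_eight(self):
        assert robust_sd(np.arange(1.0, 9.0)) == \
            pytest.approx(3.5 / 1.34898, abs=1e-4)

    def test_constant_values_warn_zero(self):
        with pytest.warns(RuntimeWarning):
            assert robust_sd(np.ones(10)) == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            robust_sd([1.0, 2.0, 3.0])


class TestDiscretize:
    def test_rule_matches_independent_recomputation(self, rng):
        v = pd.Series(rng.normal(size=200))
        lab = discretize(v)
        q1, q3 = np.percentile(v, [25, 75])
        rsd = (q3 - q1) / (2 * sps.norm.ppf(0.75))
        med = np.median(v)
        expected_fast = v < med - rsd / 2
        expected_slow = v > med + rsd / 2
        assert ((lab.labels == "fast") == expected_fast).all()
        assert ((lab.labels == "slow") == expected_slow).all()

    def test_gaussian_sample_near_terciles(self):
        # cutpoints sit at median -+ robust_sd/2 = -+0.5 sigma for a normal
        # population, so the subgroup fractions are Phi(-0.5) = 0.3085 at
        # the extremes and 0.383 in between -- approximately terciles
        r = np.random.default_rng(0)
        lab = discretize(pd.Series(r.normal(size=50000)))
        fracs = lab.labels.value_counts(normalize=True)
        assert fracs["fast"] == pytest.approx(sps.norm.cdf(-0.5), abs=0.01)
        assert fracs["intermediate"] == pytest.approx(
            1 - 2 * sps.norm.cdf(-0.5), abs=0.01)
        assert fracs["slow"] == pytest.approx(sps.norm.cdf(-0.5), abs=0.01)
        assert 0.25 < fracs["fast"] < 0.42

    def test_bimodal_modes_recovered(self):
        r = np.random.default_rng(1)
        fast_true = np.concatenate([np.zeros(50), np.ones(50)]).astype(bool)
        v = pd.Series(np.where(fast_true, -10.0, 10.0) + r.normal(0, 0.5, 100))
        lab = discretize(v)
        assert (lab.labels[fast_true] == "fast").all()
        assert (lab.labels[~fast_true] == "slow").all()

    def test_zero_robust_sd_all_intermediate(self):
        v = pd.Series([1.0] * 10 + [5.0])
        with pytest.warns(RuntimeWarning):
            lab = discretize(v)
        assert (lab.labels == "intermediate").all()

    def test_binary_encoding(self, rng):
        lab = discretize(pd.Series(rng.normal(size=50)))
        b = lab.binary()
        assert set(b.dropna()) <= {0.0, 1.0}
        assert b.isna().equals(lab.labels == "intermediate")


class TestAucScore:
    def test_worked_six_subject_site(self):
        # concordant pairs counted by hand: 3 + 3 + 2 = 8 of 9
        y = [1, 1, 1, 0, 0, 0]
        d = [0.9, 0.8, 0.7, 0.6, 0.75, 0.1]
        assert auc_score(y, d) == pytest.approx(8 / 9)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_pair_counting(self, seed):
        r = np.random.default_rng(seed)
        n = 30
        y = r.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        d = np.round(r.normal(size=n), 1)  # ties likely
        pos, neg = d[y == 1], d[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc_score(y, d) == pytest.approx(wins / (len(pos) * len(neg)))


class TestElasticNet:
    def test_separable_data_training_auc_one(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, (20, 2)),
                       rng.normal(2, 0.3, (20, 2))])
        y = np.repeat([0, 1], 20)
        m = fit_elasticnet_logistic(X, y, ModelSpec.fast(), seed=0)
        assert auc_score(y, m.decision_values(X)) == 1.0

    def test_huge_penalty_kills_weights(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.repeat([0, 1], 15)
        m = fit_elasticnet_logistic(
            X, y, ModelSpec(lambdas=(1e6,), alphas=(0.5,)), seed=0)
        assert np.abs(m.coef).max() < 1e-4

    def test_lasso_path_selects_informative_feature(self, rng):
        n = 60
        informative = rng.normal(size=n)
        X = np.column_stack([informative] + [rng.normal(size=n)
                                             for _ in range(50)])
        y = (informative > 0).astype(int)
        m = fit_elasticnet_logistic(
            X, y, ModelSpec(lambdas=(5.0,), alphas=(1.0,)), seed=0)
        nz = np.nonzero(np.abs(m.coef) > 1e-8)[0]
        assert 0 in nz and len(nz) <= 5

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_elasticnet_logistic(rng.normal(size=(10, 3)), np.ones(10))


def make_loso_problem(n_per_site=20, n_sites=4, n_feat=30, effect=2.0,
                      seed=0):
    r = np.random.default_rng(seed)
    n = n_per_site * n_sites
    sites = np.repeat(np.arange(n_sites), n_per_site)
    y = np.tile(np.repeat([0.0, 1.0], n_per_site // 2), n_sites)
    X = r.normal(size=(n, n_feat))
    X[:, :5] += effect * y[:, None]
    return X, y, sites


class TestLosoCv:
    def test_planted_effect_recovered_per_site(self):
        X, y, sites = make_loso_problem(effect=3.0)
        res = loso_cv(X, y, sites, ModelSpec.fast(), seed=0)
        mean_auc, _, per_site = site_avg_auc(res.decisions, y, sites,
                                             n_boot=0)
        assert mean_auc > 0.9
        assert len(per_site) == 4

    def test_intermediates_scored_but_not_trained_on(self):
        X, y, sites = make_loso_problem(effect=3.0)
        y_with_nan = y.copy()
        y_with_nan[::5] = np.nan
        res = loso_cv(X, y_with_nan, sites, ModelSpec.fast(), seed=0)
        assert np.isfinite(res.decisions).all()

    def test_fewer_than_two_sites_rejected(self):
        X, y, sites = make_loso_problem(n_sites=1)
        with pytest.raises(ValueError):
            loso_cv(X, y, np.zeros(len(y)), ModelSpec.fast())

    def test_no_leakage_perturbing_heldout_rows(self):
        # fitted parameters (incl. preprocessing) must depend only on
        # training-site rows: perturb held-out-site rows and compare exactly
        X, y, sites = make_loso_problem(n_per_site=12, n_feat=10, seed=3)
        meta = pd.DataFrame({
            "group": np.where(y == 0, "control", "preHD"),
            "age": np.random.default_rng(0).uniform(30, 60, len(y)),
            "sex": np.random.default_rng(1).choice(["F", "M"], len(y)),
        })
        spec = ModelSpec.fast()
        res1 = loso_cv(X, y, sites, spec, meta=meta,
                       preprocessor_factories=(AgeSexCorrector,), seed=0)
        X2 = X.copy()
        X2[sites == 0] += 100.0       # wreck the held-out site's features
        meta2 = meta.copy()
        meta2.loc[sites == 0, "age"] = 99.0
        res2 = loso_cv(X2, y, sites, spec, meta=meta2,
                       preprocessor_factories=(AgeSexCorrector,), seed=0)
        m1, m2 = res1.models[0], res2.models[0]
        np.testing.assert_array_equal(m1.coef, m2.coef)
        assert m1.intercept == m2.intercept
        np.testing.assert_array_equal(m1.feature_mean, m2.feature_mean)
        np.testing.assert_array_equal(m1.preprocessors[0].beta_,
                                      m2.preprocessors[0].beta_)

    def test_age_sex_correction_requires_controls(self, rng):
        X = rng.normal(size=(10, 4))
        meta = pd.DataFrame({"group": ["preHD"] * 10,
                             "age": rng.uniform(30, 60, 10),
                             "sex": ["F"] * 10})
        with pytest.raises(ValueError, match="controls"):
            AgeSexCorrector().fit(X, meta)

    def test_age_effect_removed_in_controls(self, rng):
        n = 200
        age = rng.uniform(30, 60, n)
        X = 0.1 * age[:, None] + rng.normal(0, 0.1, (n, 3))
        meta = pd.DataFrame({"group": ["control"] * n, "age": age,
                             "sex": rng.choice(["F", "M"], n)})
        Xc = AgeSexCorrector().fit(X, meta).transform(X, meta)
        for j in range(3):
            assert abs(np.corrcoef(Xc[:, j], age)[0, 1]) < 0.05


class TestSiteAvgAuc:
    def test_perfect_separation(self):
        y = np.tile([0.0, 0, 1, 1], 2)
        d = np.tile([0.0, 0.1, 1, 1.1], 2)
        sites = np.repeat([0, 1], 4)
        mean_auc, boot, _ = site_avg_auc(d, y, sites, n_boot=200, seed=0)
        assert mean_auc == 1.0 and boot == 1.0

    def test_independent_decisions_near_half(self):
        r = np.random.default_rng(0)
        n = 2000
        y = r.integers(0, 2, n).astype(float)
        d = r.normal(size=n)
        sites = r.integers(0, 4, n)
        mean_auc, _, _ = site_avg_auc(d, y, sites, n_boot=0)
        assert mean_auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_site_excluded_with_warning(self):
        y = np.array([0.0, 1, 0, 1, 1, 1])
        d = np.arange(6.0)
        sites = np.array([0, 0, 0, 0, 1, 1])
        with pytest.warns(RuntimeWarning, match="lacks both"):
            _, _, per_site = site_avg_auc(d, y, sites, n_boot=0)
        assert set(per_site) == {0}


class TestPooledSpearman:
    def test_fixed_point(self):
        # both sites have sample Spearman rho exactly 0.5
        x = [1, 2, 3, 4, 5]
        y = [2, 4, 1, 3, 5]
        d = np.array(x + x, dtype=float)
        v = np.array(y + y, dtype=float)
        sites = np.repeat([0, 1], 5)
        rho, per_site = pooled_spearman(d, v, sites)
        assert rho == pytest.approx(0.5)

    def test_fisher_pooling_closed_form(self):
        x = [1, 2, 3, 4, 5]
        y05 = [2, 4, 1, 3, 5]     # rho = 0.5
        y08 = [2, 1, 4, 3, 5]     # sum d^2 = 4 -> rho = 0.8
        d = np.array(x + x, dtype=float)
        v = np.array(y05 + y08, dtype=float)
        sites = np.repeat([0, 1], 5)
        rho, per_site = pooled_spearman(d, v, sites)
        assert per_site[0] == pytest.approx(0.5)
        assert per_site[1] == pytest.approx(0.8)
        assert rho == pytest.approx(np.tanh((np.arctanh(0.5)
                                             + np.arctanh(0.8)) / 2))

    def test_anticorrelated_sites_cancel(self):
        x = np.arange(6.0)
        sites = np.repeat([0, 1], 6)
        d = np.concatenate([x, x])
        v = np.concatenate([x, -x])
        rho, _ = pooled_spearman(d, v, sites)
        assert rho == pytest.approx(0.0, abs=1e-12)

    def test_small_site_excluded(self):
        d = np.array([1.0, 2, 3, 4, 1, 2])
        v = np.array([1.0, 2, 3, 4, 2, 1])
        sites = np.array([0, 0, 0, 0, 1, 1])
        with pytest.warns(RuntimeWarning, match="excluded"):
            rho, per_site = pooled_spearman(d, v, sites)
        assert set(per_site) == {0}


class TestPermutationPvalue:
    def test_low_observed_gives_large_p(self):
        r = np.random.default_rng(0)
        labels = np.tile([0, 1], 20)
        sites = np.repeat([0, 1], 20)
        d = r.normal(size=40)

        def stat(y):
            return auc_score(y.astype(int), d)

        p = permutation_pvalue(0.1, stat, labels, sites, n_perm=200, seed=1)
        assert p > 0.5

    def test_add_one_rule_floor(self):
        labels = np.tile([0, 1], 10)
        sites = np.zeros(20)
        d = labels.astype(float)  # perfectly separating

        def stat(y):
            return auc_score(y.astype(int), d)

        p = permutation_pvalue(1.0, stat, labels, sites, n_perm=99, seed=0)
        assert p >= 1 / 100
        assert p <= 5 / 100

    def test_degenerate_labels_warn_p_one(self):
        with pytest.warns(RuntimeWarning):
            p = permutation_pvalue(1.0, lambda y: 0.0, np.ones(10),
                                   np.zeros(10), n_perm=10)
        assert p == 1.0


class TestGeneticFeature:
    def test_cag_linked_labels_benefit(self, rng):
        n = 80
        cag = rng.integers(39, 50, n)
        y = (cag > np.median(cag)).astype(int)
        X = rng.normal(size=(n, 20))            # uninformative features
        X_aug = add_genetic_feature(X, cag)
        assert X_aug.shape == (n, 21)
        m0 = fit_elasticnet_logistic(X, y, ModelSpec.fast(), seed=0)
        m1 = fit_elasticnet_logistic(X_aug, y, ModelSpec.fast(), seed=0)
        assert auc_score(y, m1.decision_values(X_aug)) > \
            auc_score(y, m0.decision_values(X))

    def test_constant_cag_no_effect(self, rng):
        X = rng.normal(size=(20, 5))
        X_aug = add_genetic_feature(X, np.full(20, 43))
        np.testing.assert_array_equal(X_aug[:, -1], 0.0)

    def test_missing_cag_rejected(self, rng):
        with pytest.raises(ValueError):
            add_genetic_feature(rng.normal(size=(4, 2)),
                                [43, np.nan, 44, 45])
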