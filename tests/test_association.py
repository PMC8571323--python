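import itertools

import numpy as np
import pytest
from scipy import stats

from endomark.association import (
    ContingencyTable2x2,
    association_table,
    fisher_exact_2x2,
    fit_logistic,
    interaction_test,
    lr_test,
    mann_whitney,
    qualify_biomarker,
)
from endomark.simulate import CohortSimConfig, generate_trial_cohort

from conftest import make_two_arm_cohort


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        fit = fit_logistic(np.ones((10, 1)), y, terms=["intercept"])
        assert fit.converged
        assert fit.coefficients["intercept"] == pytest.approx(np.log(3 / 7), abs=1e-8)

    def test_saturated_two_by_two_equals_log_odds_ratio(self):
        # groups of 10: group 0 has 2 successes, group 1 has 7
        g = np.repeat([0.0, 1.0], 10)
        y = np.concatenate([np.repeat([1.0, 0.0], [2, 8]), np.repeat([1.0, 0.0], [7, 3])])
        fit = fit_logistic(np.column_stack([np.ones(20), g]), y, terms=["int", "g"])
        lor = np.log((7 / 3) / (2 / 8))
        assert fit.coefficients["g"] == pytest.approx(lor, abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_loglik_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=60)
        y = (rng.random(60) < 1 / (1 + np.exp(-(0.4 + 0.8 * x)))).astype(float)
        X = np.column_stack([np.ones(60), x])
        fit = fit_logistic(X, y, terms=["b0", "b1"])
        # two-stage brute-force grid over the coefficient plane
        b0 = np.linspace(-3, 3, 121)
        b1 = np.linspace(-3, 3, 121)

        def grid_max(b0g, b1g):
            eta = X @ np.stack(np.meshgrid(b0g, b1g, indexing="ij"), 0).reshape(2, -1)
            ll = y @ eta - np.logaddexp(0, eta).sum(axis=0)
            i = np.argmax(ll)
            return ll[i], b0g[i // len(b1g)], b1g[i % len(b1g)]

        ll1, c0, c1 = grid_max(b0, b1)
        ll2, _, _ = grid_max(
            np.linspace(c0 - 0.06, c0 + 0.06, 61), np.linspace(c1 - 0.06, c1 + 0.06, 61)
        )
        assert fit.loglik >= ll2 - 1e-12
        assert abs(fit.loglik - ll2) < 1e-4

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        X = np.column_stack([np.ones(80), rng.normal(size=80), rng.normal(size=80)])
        y = (rng.random(80) < 0.4).astype(float)
        fit = fit_logistic(X, y, terms=["a", "b", "c"])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)
        np.testing.assert_allclose(
            list(fit.coefficients.values()), ref.params, atol=1e-6
        )
        np.testing.assert_allclose(
            list(fit.standard_errors.values()), ref.bse, atol=1e-5
        )

    def test_separation_flagged_not_raised(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = (x > 0).astype(float)
        fit = fit_logistic(np.column_stack([np.ones(6), x]), y)
        assert not fit.converged
        assert fit.diagnostic

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.ones((5, 1)), np.ones(5))

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(8), np.ones(8)])
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(X, y)


class TestLRTest:
    def test_identical_models_give_p_one(self):
        y = np.array([1, 0, 1, 0, 1, 0, 0, 0], dtype=float)
        full = fit_logistic(np.ones((8, 1)), y, terms=["int"])
        full2 = fit_logistic(
            np.column_stack([np.ones(8), np.zeros(8) + [1, 0, 1, 0, 1, 0, 1, 0]]),
            y,
            terms=["int", "x"],
        )
        stat, p = lr_test(full2, full)
        assert stat >= 0
        # chi2 quantile identity: stat 3.841 ~ p 0.05
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_non_nested_rejected(self):
        y = np.array([1, 0, 1, 0, 1, 0], dtype=float)
        a = fit_logistic(np.ones((6, 1)), y, terms=["int"])
        b = fit_logistic(np.ones((6, 1)), y, terms=["other"])
        with pytest.raises(ValueError, match="nested"):
            lr_test(a, b)

    @pytest.mark.parametrize("seed", range(3))
    def test_p_matches_chi2_survival(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(float)
        X = np.column_stack([np.ones(40), x])
        full = fit_logistic(X, y, terms=["int", "x"])
        red = fit_logistic(X[:, :1], y, terms=["int"])
        stat, p = lr_test(full, red)
        assert p == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-12)


class TestQualifyAndInteraction:
    def test_null_biomarker_p_uniform(self, null_config_kwargs):
        ps = []
        for s in range(200):
            cohort = generate_trial_cohort(CohortSimConfig(seed=s, **null_config_kwargs))
            try:
                ps.append(qualify_biomarker(cohort, "RAB5A", "TDM1P").p)
            except ValueError:
                continue
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_biomarker_rejected(self):
        cohort = make_two_arm_cohort(
            [1.0] * 20, [0, 1] * 10, [1.0] * 20, [0, 1] * 10
        )
        with pytest.raises(ValueError, match="variance"):
            qualify_biomarker(cohort, "RAB5A", "TDM1P")

    def test_coefficient_scale_is_per_sd(self):
        # rescaling raw expression must leave the per-SD coefficient unchanged
        rng = np.random.default_rng(2)
        x = rng.normal(10, 1, 60)
        y = rng.random(60) < 1 / (1 + np.exp(-(x - 10)))
        cohort = make_two_arm_cohort(x, y, rng.normal(10, 1, 30), rng.random(30) < 0.3)
        a = qualify_biomarker(cohort, "RAB5A", "TDM1P")
        cohort2 = cohort.assign(RAB5A=5.0 * cohort["RAB5A"] - 7.0)
        b = qualify_biomarker(cohort2, "RAB5A", "TDM1P")
        assert a.coef == pytest.approx(b.coef, abs=1e-6)
        assert a.lr_stat == pytest.approx(b.lr_stat, abs=1e-6)
        assert a.odds_ratio_per_sd == pytest.approx(np.exp(a.coef))

    def test_interaction_power_with_strong_effect(self):
        hits = 0
        cfg = dict(
            n_per_arm={"TDM1P": 500, "TH": 500},
            biomarker_mean={"TDM1P": 0.0, "TH": 0.0},
            biomarker_sd=1.0,
            beta0=-1.0,
            beta_arm=0.3,
            beta_marker=0.0,
            beta_interaction=1.0,
            beta_hr=0.0,
        )
        n_reps = 40
        for s in range(n_reps):
            cohort = generate_trial_cohort(CohortSimConfig(seed=s, **cfg))
            res = interaction_test(cohort, "RAB5A", ("TDM1P", "TH"))
            hits += res.p < 0.001
        assert hits >= 0.95 * n_reps

    def test_single_arm_input_rejected(self):
        cohort = make_two_arm_cohort(
            np.arange(20), [0, 1] * 10, [], []
        )
        with pytest.raises(ValueError, match="both arms"):
            interaction_test(cohort, "RAB5A", ("TDM1P", "TH"))

    def test_association_table_shape_and_content(self, default_cohort):
        tab = association_table(default_cohort, ["RAB4A", "RAB5A", "RAB11A"], ("TDM1P", "TH"))
        assert len(tab) == 9  # 3 markers x (2 arms + interaction)
        assert (tab["coef_sign"] == np.sign(tab["coef"])).all()
        np.testing.assert_allclose(tab["neg_log10_p"], -np.log10(tab["p"]))
        np.testing.assert_allclose(tab["odds_ratio_per_sd"], np.exp(tab["coef"]))


class TestFisherExact:
    def test_perfectly_crossed_table(self):
        # [[0,5],[5,0]]: only 2 of the 252 equally-extreme arrangements
        p = fisher_exact_2x2(ContingencyTable2x2(0, 5, 5, 0))
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_hr_balance_table_reproduces_half(self):
        # 12/40 vs 5/12 HR-negative
        p = fisher_exact_2x2(ContingencyTable2x2(12, 28, 5, 7))
        assert p == pytest.approx(0.4959, abs=5e-4)

    def test_symmetric_under_row_and_column_swaps(self):
        p = fisher_exact_2x2(ContingencyTable2x2(3, 9, 6, 2))
        assert fisher_exact_2x2(ContingencyTable2x2(6, 2, 3, 9)) == pytest.approx(p)
        assert fisher_exact_2x2(ContingencyTable2x2(9, 3, 2, 6)) == pytest.approx(p)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="margin"):
            assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestMannWhitney:
    def test_tiny_example_exact(self):
        u, p = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert u == 0
        assert p == pytest.approx(2 / 6, rel=1e-12)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.5, 2.5, 0.5])
        assert 0 < p <= 1.0
        _, p2 = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p2 == pytest.approx(1.0)

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        y = rng.normal(0.5, 1, size=11)
        u_obs, p = mann_whitney(x, y)
        # enumeration oracle: all C(19,8) assignments of the pooled values
        pooled = np.concatenate([x, y])
        order = np.argsort(pooled)
        ranks = np.empty(19)
        ranks[order] = np.arange(1, 20)
        us = []
        for combo in itertools.combinations(range(19), 8):
            r = ranks[list(combo)].sum()
            us.append(r - 8 * 9 / 2)
        us = np.array(us)
        p_lo = np.mean(us <= u_obs)
        p_hi = np.mean(us >= u_obs)
        p_enum = min(1.0, 2 * min(p_lo, p_hi))
        assert p == pytest.approx(p_enum, rel=1e-9)
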