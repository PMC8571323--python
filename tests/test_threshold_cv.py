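import numpy as np
import pytest
from scipy import stats

from endomark.simulate import CohortSimConfig, generate_trial_cohort
from endomark.threshold_cv import (
    CVConfig,
    candidate_thresholds,
    combine_logit,
    interaction_p_at_threshold,
    run_cv,
    split_balanced,
)

from conftest import make_two_arm_cohort


class TestSplitBalanced:
    def test_even_strata_split_in_half(self):
        rng = np.random.default_rng(0)
        x = np.arange(80.0)
        y = np.tile([0, 1], 40)
        cohort = make_two_arm_cohort(x[:40], y[:40], x[40:], y[40:])
        train, test = split_balanced(cohort, rng)
        for arm in ("TDM1P", "TH"):
            for pcr in (False, True):
                stratum_train = ((train["arm"] == arm) & (train["pcr"] == pcr)).sum()
                assert stratum_train == 10
        assert len(train) + len(test) == 80
        assert set(train["patient_id"]).isdisjoint(test["patient_id"])

    def test_trial_size_half_split(self, default_cohort):
        cohort = default_cohort[default_cohort["arm"].isin(["TDM1P", "TH"])]
        rng = np.random.default_rng(1)
        train, _ = split_balanced(cohort, rng)
        # 83 patients split into balanced halves
        assert len(train) in range(38, 46)

    def test_same_seed_identical_split(self, default_cohort):
        a_train, _ = split_balanced(default_cohort, np.random.default_rng(5))
        b_train, _ = split_balanced(default_cohort, np.random.default_rng(5))
        assert list(a_train["patient_id"]) == list(b_train["patient_id"])


class TestCandidateThresholds:
    def test_percentile_window_on_one_to_ten(self):
        # P10 = 1.9 and P90 = 9.1 under linear interpolation
        cands = candidate_thresholds(np.arange(1.0, 11.0))
        np.testing.assert_array_equal(cands, np.arange(2.0, 10.0))

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            candidate_thresholds(np.full(10, 3.0))

    def test_full_window_returns_all_unique(self):
        x = np.array([3.0, 1.0, 2.0, 2.0, 5.0, 4.0])
        np.testing.assert_array_equal(
            candidate_thresholds(x, (0, 100)), np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        )


class TestInteractionPAtThreshold:
    def test_threshold_below_all_values_skipped(self, default_cohort):
        assert interaction_p_at_threshold(default_cohort, -100.0) is None

    def test_matches_general_logistic_route(self, default_cohort):
        # aggregated-cell fast path must agree with the row-level fit
        from endomark.association import fit_logistic, lr_test

        sub = default_cohort[default_cohort["arm"].isin(["TDM1P", "TH"])]
        thr = float(np.median(sub["RAB5A"]))
        p_fast = interaction_p_at_threshold(sub, thr)
        g = (sub["RAB5A"].to_numpy() >= thr).astype(float)
        t = (sub["arm"] == "TDM1P").to_numpy(dtype=float)
        y = sub["pcr"].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(sub)), g, t, g * t])
        full = fit_logistic(X, y, terms=["i", "g", "t", "gt"])
        red = fit_logistic(X[:, :3], y, terms=["i", "g", "t"])
        _, p_slow = lr_test(full, red)
        assert p_fast == pytest.approx(p_slow, abs=1e-8)

    def test_breakpoint_threshold_beats_off_breakpoint(self, strong_interaction_cohort):
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            cfg = CohortSimConfig(
                seed=300 + s,
                n_per_arm={"TDM1P": 200, "TH": 200},
                biomarker_mean={"TDM1P": 10.35, "TH": 10.35},
                beta0=-1.1,
                beta_arm=-0.63,
                beta_marker=0.0,
                beta_interaction=2.58,
                beta_hr=0.0,
                breakpoint=10.35,
            )
            cohort = generate_trial_cohort(cfg)
            p_bp = interaction_p_at_threshold(cohort, 10.35)
            p_off = interaction_p_at_threshold(cohort, 10.35 + 0.8)
            if p_bp is not None and p_off is not None and p_bp < p_off:
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestCombineLogit:
    def test_two_halves_give_half(self):
        c = combine_logit([0.5, 0.5])
        assert c.t_stat == pytest.approx(0.0, abs=1e-12)
        assert c.p == pytest.approx(0.5, abs=1e-12)
        assert c.df == 14

    def test_single_p_formula(self):
        # hand evaluation of the k=1 statistic and its t reference
        c = combine_logit([0.05])
        t_manual = np.log(19) / np.sqrt(np.pi**2 * 7 / (3 * 9))
        assert c.t_stat == pytest.approx(t_manual, rel=1e-12)
        assert c.df == 9
        assert c.p == pytest.approx(stats.t.sf(t_manual, 9), rel=1e-12)

    def test_null_calibration_of_combination(self):
        rng = np.random.default_rng(0)
        combined = [combine_logit(rng.uniform(size=25)).p for _ in range(500)]
        assert stats.kstest(combined, "uniform").pvalue > 0.01

    def test_degenerate_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            c = combine_logit([1.0, 0.5])
        assert 0 < c.p < 1


class TestRunCV:
    def test_recovers_generative_breakpoint(self, strong_interaction_cohort):
        result = run_cv(
            strong_interaction_cohort, config=CVConfig(n_iterations=25, seed=0)
        )
        assert abs(result.selected_threshold - 10.35) <= 0.25
        assert result.overall_p.p < 0.01

    def test_selected_threshold_in_percentile_window(self, default_cohort):
        result = run_cv(default_cohort, config=CVConfig(n_iterations=10, seed=3))
        sub = default_cohort[default_cohort["arm"].isin(["TDM1P", "TH"])]
        lo, hi = np.percentile(sub["RAB5A"], [10, 90])
        # pooled window is wider than any training window
        assert lo - 0.5 <= result.selected_threshold <= hi + 0.5
        assert result.selected_threshold in result.combined_p_by_threshold

    def test_deterministic_given_seed(self, default_cohort):
        a = run_cv(default_cohort, config=CVConfig(n_iterations=8, seed=9))
        b = run_cv(default_cohort, config=CVConfig(n_iterations=8, seed=9))
        assert a.selected_threshold == b.selected_threshold
        assert a.overall_p.p == b.overall_p.p
        assert [r.test_p for r in a.iterations] == [r.test_p for r in b.iterations]

    def test_row_order_invariance(self, default_cohort):
        shuffled = default_cohort.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = run_cv(default_cohort, config=CVConfig(n_iterations=8, seed=2))
        b = run_cv(shuffled, config=CVConfig(n_iterations=8, seed=2))
        assert a.selected_threshold == b.selected_threshold
        assert a.overall_p.p == pytest.approx(b.overall_p.p, rel=1e-12)

    def test_single_iteration_result(self, strong_interaction_cohort):
        result = run_cv(strong_interaction_cohort, config=CVConfig(n_iterations=1, seed=5))
        (rec,) = [r for r in result.iterations]
        assert result.selected_threshold == rec.selected_threshold
        assert result.overall_p.k == 1

    def test_combine_all_grouping_selects_modal_threshold(self, strong_interaction_cohort):
        per = run_cv(
            strong_interaction_cohort,
            config=CVConfig(n_iterations=15, seed=6),
            grouping="per_threshold",
        )
        modal = run_cv(
            strong_interaction_cohort,
            config=CVConfig(n_iterations=15, seed=6),
            grouping="combine_all",
        )
        counts = {}
        for r in modal.iterations:
            if r.selected_threshold is not None and r.test_p is not None:
                counts[r.selected_threshold] = counts.get(r.selected_threshold, 0) + 1
        top = max(counts.values())
        assert modal.selected_threshold == min(t for t, c in counts.items() if c == top)
        assert modal.overall_p.p == pytest.approx(per.overall_p.p)
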