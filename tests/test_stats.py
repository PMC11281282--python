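import numpy as np
import pandas as pd
import pytest

from shgfiber import (
    CohortParams,
    fit_random_intercept,
    generate_cohort,
    kaplan_meier,
    logrank_and_hr,
    median_split,
    ttest_one_tailed,
)

from _oracles import kaplan_meier_oracle, pooled_ttest_oracle


class TestTTest:
    def test_identical_groups_give_null_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = ttest_one_tailed(a, a.copy())
        assert res.t == 0.0
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.p_one_sided == pytest.approx(0.5)

    def test_years_smoked_summary_comparison(self):
        """Pooled test from published-style summary stats (two groups of
        smokers, mean +- sd over n) lands on the printed p within rounding."""
        res = ttest_one_tailed((42.0, 6.5, 12), (47.9, 6.6, 14), alternative="less")
        assert res.df == 24
        assert res.p_two_sided == pytest.approx(0.0326, abs=0.003)

    def test_matches_textbook_formula_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n1, n2 = rng.integers(3, 12, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n1)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n2)
            t, df, p = pooled_ttest_oracle(a, b)
            res = ttest_one_tailed(a, b)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.df == df
            assert res.p_two_sided == pytest.approx(p, abs=1e-10)

    def test_raw_and_summary_inputs_agree(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1.2, 14)
        raw = ttest_one_tailed(a, b)
        summ = ttest_one_tailed(
            (a.mean(), a.std(ddof=1), len(a)), (b.mean(), b.std(ddof=1), len(b))
        )
        assert abs(raw.p_two_sided - summ.p_two_sided) < 1e-12
        assert abs(raw.p_one_sided - summ.p_one_sided) < 1e-12

    def test_zero_variance_everywhere_raises(self):
        with pytest.raises(ValueError):
            ttest_one_tailed(np.ones(5), np.ones(5))

    def test_one_sided_p_halves_two_sided_when_sign_matches(self):
        res = ttest_one_tailed(np.array([5.0, 6, 7, 8]), np.array([1.0, 2, 3, 4]))
        assert res.p_one_sided == pytest.approx(res.p_two_sided / 2)


class TestRandomIntercept:
    def test_exchangeable_patients_match_simple_log_mean_difference(self):
        fovs, _ = generate_cohort(CohortParams(sd_between=0.0, seed=6))
        fit = fit_random_intercept(fovs)
        logs = np.log(fovs["percent_fiber_volume"])
        simple = (
            logs[fovs["group"] == "recurrent"].mean()
            - logs[fovs["group"] == "non_recurrent"].mean()
        )
        assert abs(fit.beta_group - simple) <= 2 * fit.se_beta

    def test_scale_equivariance_of_group_effect(self, small_cohort):
        fovs, _ = small_cohort
        fit1 = fit_random_intercept(fovs)
        scaled = fovs.assign(percent_fiber_volume=fovs["percent_fiber_volume"] * 3.7)
        fit2 = fit_random_intercept(scaled)
        assert fit2.beta_group == pytest.approx(fit1.beta_group, rel=1e-6)

    def test_nonpositive_volumes_error_by_default_and_offset_on_request(self, small_cohort):
        fovs, _ = small_cohort
        bad = fovs.copy()
        bad.loc[0, "percent_fiber_volume"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            fit_random_intercept(bad)
        fit = fit_random_intercept(bad, zero_policy="offset")
        assert np.isfinite(fit.beta_group)

    def test_power_increases_with_effect_size(self):
        reps = 150
        powers = []
        for k, eff in enumerate((0.0, 0.25, 0.5)):
            rej = 0
            for s in range(reps):
                fovs, _ = generate_cohort(
                    CohortParams(
                        n_patients_per_group=(12, 14),
                        group_effect_log=eff,
                        seed=300000 + 1000 * k + s,
                    )
                )
                rej += fit_random_intercept(fovs).p_one_sided < 0.05
            powers.append(rej / reps)
        assert powers[0] < powers[1] < powers[2]

    def test_fov_level_model_usually_beats_patient_level_t(self):
        """With large within-patient scatter the FOV-level mixed model is
        more sensitive than the t-test on patient means, explaining why the
        analysis chain runs both."""
        wins = 0
        reps = 200
        for s in range(reps):
            fovs, pats = generate_cohort(
                CohortParams(
                    n_patients_per_group=(12, 14),
                    group_effect_log=0.5,
                    sd_within=1.2,
                    seed=400000 + s,
                )
            )
            mm = fit_random_intercept(fovs)
            a = pats.loc[pats["group"] == "recurrent", "mean_volume"].to_numpy()
            b = pats.loc[pats["group"] == "non_recurrent", "mean_volume"].to_numpy()
            tt = ttest_one_tailed(a, b)
            wins += mm.p_one_sided < tt.p_one_sided
        assert wins / reps > 0.5


def patients_frame(volumes, times=None, events=None):
    n = len(volumes)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "group": ["recurrent"] * n,
            "mean_volume": volumes,
            "time": times if times is not None else np.arange(1.0, n + 1),
            "event": events if events is not None else np.ones(n, dtype=int),
        }
    )


class TestMedianSplit:
    def test_even_cohort_splits_above_median(self):
        split = median_split(patients_frame([1.0, 2.0, 3.0, 4.0]))
        assert split.threshold == 2.5
        assert sorted(split.high["mean_volume"]) == [3.0, 4.0]

    def test_tie_at_median_goes_low(self):
        split = median_split(patients_frame([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert split.threshold == 3.0
        assert 3.0 in split.low["mean_volume"].values
        assert sorted(split.high["mean_volume"]) == [4.0, 5.0]

    def test_groups_partition_cohort(self):
        pats = patients_frame(np.random.default_rng(3).random(11) * 20)
        split = median_split(pats)
        assert len(split.high) + len(split.low) == len(pats)
        combined = pd.concat([split.high, split.low])["patient_id"]
        assert set(combined) == set(pats["patient_id"])

    def test_identical_volumes_raise(self):
        with pytest.raises(ValueError, match="identical"):
            median_split(patients_frame([2.0] * 6))


class TestKaplanMeier:
    def test_no_events_gives_flat_curve(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_worked_example_matches_hand_computation(self):
        km = kaplan_meier([1, 2, 3, 4, 5], [1, 0, 1, 1, 0])
        assert km.at(1) == pytest.approx(0.8)
        assert km.at(3) == pytest.approx(0.5333333333)
        assert km.at(4) == pytest.approx(0.2666666667)

    def test_all_distinct_events_closed_form(self):
        n = 7
        km = kaplan_meier(np.arange(1.0, n + 1), np.ones(n, dtype=int))
        for k in range(1, n + 1):
            assert km.at(k) == pytest.approx((n - k) / n)

    def test_matches_hand_product_limit_on_random_data(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5, 40).round(2) + 0.01
        events = rng.integers(0, 2, 40)
        oracle = kaplan_meier_oracle(times, events)
        km = kaplan_meier(times, events)
        for t, s in oracle.items():
            assert km.at(t) == pytest.approx(s, abs=1e-9)

    def test_curve_is_monotone_in_unit_interval(self):
        rng = np.random.default_rng(9)
        km = kaplan_meier(rng.exponential(3, 50) + 0.01, rng.integers(0, 2, 50))
        assert np.all(np.diff(km.survival) <= 0)
        assert km.survival.min() >= 0 and km.survival.max() <= 1


class TestLogrank:
    def test_identical_groups_are_null(self):
        g = patients_frame([1.0] * 4, times=[1, 2, 3, 4.0], events=[1, 0, 1, 1])
        res = logrank_and_hr(g, g.copy(), cox=False)
        assert res.chi2 == 0.0
        assert res.hr == 1.0

    def test_toy_example_matches_hand_hypergeometric_sums(self):
        high = patients_frame([1, 1], times=[1.0, 4.0], events=[1, 0])
        low = patients_frame([1, 1], times=[2.0, 5.0], events=[1, 0])
        res = logrank_and_hr(high, low, cox=False)
        assert res.e_high == pytest.approx(5 / 6)
        assert res.chi2 == pytest.approx(1 / 17)
        assert res.hr == pytest.approx(1.4)

    def test_chi2_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(12)
        high = patients_frame(
            np.ones(20), times=rng.exponential(2, 20) + 0.01, events=rng.integers(0, 2, 20)
        )
        low = patients_frame(
            np.ones(25), times=rng.exponential(4, 25) + 0.01, events=rng.integers(0, 2, 25)
        )
        res = logrank_and_hr(high, low, cox=False)
        ref = logrank_test(high["time"], low["time"], high["event"], low["event"])
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_raise(self):
        g = patients_frame([1.0] * 3, times=[1, 2, 3.0], events=[0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            logrank_and_hr(g, g.copy())

    def test_estimators_consistent_at_large_n_with_known_hazard_ratio(self):
        """Exponential groups with a true hazard ratio of 3: the Cox
        partial-likelihood HR is consistent, while the O/E estimator is
        known to attenuate large ratios somewhat."""
        rng = np.random.default_rng(1)
        high = patients_frame(
            np.ones(2000), times=rng.exponential(1, 2000) + 1e-3, events=np.ones(2000, int)
        )
        low = patients_frame(
            np.ones(2000), times=rng.exponential(3, 2000) + 1e-3, events=np.ones(2000, int)
        )
        res = logrank_and_hr(high, low)
        assert res.cox_hr == pytest.approx(3.0, rel=0.10)
        assert 2.0 <= res.hr <= res.cox_hr
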