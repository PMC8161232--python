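import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vocamood.screening import (CohortValidationError, InfeasiblePowerError,
                                ScreeningModel, assign_groups, best_cutpoint,
                                cohens_d, evaluate_cohort, pearson_r,
                                power_two_sample_t, required_n_two_sample_t,
                                roc_auc, tukey_kramer)
from vocamood.synthetic import simulate_vitality_cohort


def brute_force_auc(pos, neg):
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAssignGroups:
    def test_hamd_cutoffs(self):
        df = pd.DataFrame({"is_patient": [True, True, True, False],
                           "hamd": [7, 8, 0, None]})
        out = assign_groups(df)
        assert list(out["group"]) == ["no_depression", "depression",
                                      "no_depression", "healthy"]

    def test_patient_without_hamd_rejected(self):
        df = pd.DataFrame({"is_patient": [True], "hamd": [None]})
        with pytest.raises(CohortValidationError, match="HAM-D"):
            assign_groups(df)


class TestPearson:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)
        assert p < 1e-8

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([0.5, 0.4, 0.36])
        r, _ = pearson_r(x, y)
        rx, ry = x - x.mean(), y - y.mean()
        expected = (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_p_uniform_under_null(self):
        # independent x and y at the study's n: p-values are U(0,1)
        rng = np.random.default_rng(12345)
        pvals = [pearson_r(rng.normal(size=46), rng.normal(size=46))[1]
                 for _ in range(2000)]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_spearman_option(self):
        x = [1, 2, 3, 4, 5]
        r, _ = pearson_r(x, np.exp(x), method="spearman")
        assert r == pytest.approx(1.0)


class TestTukeyKramer:
    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)  # 5 pooled SDs apart
        p = tukey_kramer({"a": a, "b": b})[("a", "b")]
        assert p < 0.001

    def test_duplicated_group_p_near_one(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 15)
        p = tukey_kramer({"a": a, "b": a.copy(), "c": rng.normal(2, 1, 15)})
        assert p[("a", "b")] > 0.99

    def test_matches_statsmodels_on_unequal_groups(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(5)
        groups = {"g1": rng.normal(0.0, 1, 14), "g2": rng.normal(0.5, 1, 24),
                  "g3": rng.normal(1.0, 1, 22)}
        ours = tukey_kramer(groups)
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = statsmodels.pairwise_tukeyhsd(values, labels)
        for (g_a, g_b), p_sm in zip(
                itertools.combinations(groups, 2), sm.pvalues):
            assert ours[(g_a, g_b)] == pytest.approx(p_sm, abs=1e-4)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_kramer({"a": [1.0], "b": [1.0, 2.0]})

    def test_familywise_type_i_error_near_nominal(self):
        # three identical populations: any significant pair is a false alarm
        rng = np.random.default_rng(99)
        false_alarms = 0
        reps = 500
        for _ in range(reps):
            groups = {k: rng.normal(0.55, 0.1, 20) for k in ("h", "n", "d")}
            if min(tukey_kramer(groups).values()) < 0.05:
                false_alarms += 1
        assert false_alarms / reps <= 0.07


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8], [0.1, 0.2])
        assert auc == 1.0

    def test_identical_groups_auc_half(self):
        auc, _ = roc_auc([0.3, 0.5, 0.7], [0.3, 0.5, 0.7])
        assert auc == pytest.approx(0.5)

    def test_matches_exhaustive_pair_count(self):
        rng = np.random.default_rng(10)
        pos = rng.normal(0.6, 0.1, 10)
        neg = rng.normal(0.5, 0.1, 10)
        auc, _ = roc_auc(pos, neg)
        assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    @given(st.lists(st.integers(0, 20), min_size=2, max_size=30),
           st.lists(st.integers(0, 20), min_size=2, max_size=30))
    @settings(derandomize=True, max_examples=100)
    def test_mann_whitney_identity_with_ties(self, pos, neg):
        # integer scores force ties; trapezoid AUC must equal the pair count
        auc, _ = roc_auc(pos, neg)
        assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [0.5])


class TestBestCutpoint:
    def test_perfect_groups_reach_j_one(self):
        _, curve = roc_auc([0.9, 0.8], [0.1, 0.2])
        cut, sens, spec = best_cutpoint(curve)
        assert sens == 1.0 and spec == 1.0
        assert 0.2 < cut <= 0.8

    def test_identical_groups_j_near_zero(self):
        _, curve = roc_auc([0.3, 0.5, 0.7], [0.3, 0.5, 0.7])
        _, sens, spec = best_cutpoint(curve)
        assert sens + spec - 1 == pytest.approx(0.0, abs=1e-12)

    def test_j_maximal_over_exhaustive_scan(self):
        rng = np.random.default_rng(21)
        pos = rng.normal(0.6, 0.1, 25)
        neg = rng.normal(0.5, 0.1, 25)
        _, curve = roc_auc(pos, neg)
        _, sens, spec = best_cutpoint(curve)
        best_j = max(
            np.mean(pos >= t) + np.mean(neg < t) - 1
            for t in np.concatenate([pos, neg]))
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)

    def test_fixed_specificity_rule(self):
        rng = np.random.default_rng(22)
        _, curve = roc_auc(rng.normal(0.6, 0.1, 50), rng.normal(0.5, 0.1, 50))
        _, sens, spec = best_cutpoint(curve, rule="fixed_specificity",
                                      min_specificity=0.9)
        assert spec >= 0.9


class TestCohensD:
    def test_identical_groups_zero(self):
        a = [0.1, 0.2, 0.3]
        assert cohens_d(a, a) == 0.0

    def test_one_sd_shift(self):
        rng = np.random.default_rng(8)
        b = rng.normal(0, 1, 2000)
        a = b + b.std(ddof=1)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_summary_statistic_construction(self):
        # groups built to match reported summaries: healthy mean 0.60
        # (SE 0.027, n 14) vs depression 0.49 (SE 0.022, n 22)
        def fixed_moments(mean, sd, n, rng):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z
        rng = np.random.default_rng(30)
        healthy = fixed_moments(0.60, 0.027 * np.sqrt(14), 14, rng)
        depression = fixed_moments(0.49, 0.022 * np.sqrt(22), 22, rng)
        d = cohens_d(healthy, depression)
        sp = np.sqrt((13 * (0.027**2 * 14) + 21 * (0.022**2 * 22)) / 34)
        assert d == pytest.approx(0.11 / sp, abs=1e-9)
        assert d == pytest.approx(1.08, abs=0.01)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestPower:
    def test_zero_effect_power_equals_alpha(self):
        assert power_two_sample_t(0.0, 20, 20, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_matches_monte_carlo_rejection_rate(self):
        rng = np.random.default_rng(77)
        n, reps, d = 20, 50_000, 1.0
        a = rng.normal(d, 1, (reps, n))
        b = rng.normal(0, 1, (reps, n))
        t = stats.ttest_ind(a, b, axis=1)
        mc = np.mean(t.pvalue < 0.05)
        assert power_two_sample_t(d, n, n) == pytest.approx(mc, abs=0.01)

    def test_matches_statsmodels(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        expected = smp.TTestIndPower().power(effect_size=1.03, nobs1=22,
                                             ratio=14 / 22, alpha=0.05)
        assert power_two_sample_t(1.03, 22, 14) == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_effect_and_n(self):
        powers_d = [power_two_sample_t(d, 20, 20) for d in (0.2, 0.5, 1.0, 1.5)]
        assert powers_d == sorted(powers_d)
        powers_n = [power_two_sample_t(0.8, n, n) for n in (5, 10, 20, 40)]
        assert powers_n == sorted(powers_n)
        assert power_two_sample_t(0.8, 20, 20, alpha=0.01) < \
               power_two_sample_t(0.8, 20, 20, alpha=0.10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_two_sample_t(1.0, 1, 20)
        with pytest.raises(ValueError):
            power_two_sample_t(1.0, 20, 20, alpha=1.5)


class TestRequiredN:
    def test_roundtrip_inversion(self):
        n = required_n_two_sample_t(1.03, 22, power=0.8)
        assert power_two_sample_t(1.03, 22, n) == pytest.approx(0.8, abs=1e-6)

    def test_monotone_decreasing_in_effect(self):
        # n_fixed = 100 keeps every sweep point feasible (the noncentrality
        # ceiling d*sqrt(n_fixed) must exceed the target's requirement)
        ns = [required_n_two_sample_t(d, 100, power=0.8)
              for d in (0.5, 1.0, 1.5, 2.0)]
        assert ns == sorted(ns, reverse=True)
        assert all(a > b for a, b in zip(ns, ns[1:]))

    def test_unattainable_power_is_infeasible(self):
        # noncentrality saturates at d*sqrt(n_fixed): tiny d cannot reach 0.8
        with pytest.raises(InfeasiblePowerError):
            required_n_two_sample_t(0.05, 4, power=0.8)
        with pytest.raises(InfeasiblePowerError):
            required_n_two_sample_t(0.0, 22, power=0.8)


class TestEvaluateCohort:
    def test_null_cohort_near_chance(self):
        aucs, any_sig = [], 0
        for seed in range(30):
            cohort = simulate_vitality_cohort(d=0.0, n_per_group=20, seed=seed)
            rep = evaluate_cohort(cohort)
            aucs.append(rep.auc)
            any_sig += min(rep.tukey_p.values()) < 0.05
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)
        assert any_sig / 30 <= 0.2

    def test_binormal_auc_identity_at_gap_one(self):
        aucs = [evaluate_cohort(
                    simulate_vitality_cohort(d=1.0, n_per_group=20, seed=s)).auc
                for s in range(200)]
        assert np.mean(aucs) == pytest.approx(stats.norm.cdf(1 / np.sqrt(2)),
                                              abs=0.02)

    def test_parameter_recovery_at_large_n(self):
        cohort = simulate_vitality_cohort(d=1.0, n_per_group=200, seed=123)
        rep = evaluate_cohort(cohort)
        assert rep.cohens_d == pytest.approx(1.0, abs=0.2)
        assert rep.auc == pytest.approx(stats.norm.cdf(1 / np.sqrt(2)), abs=0.05)
        assert rep.pearson_r < 0  # severity runs against vitality

    def test_single_row_group_is_informative_error(self):
        cohort = simulate_vitality_cohort(d=1.0, n_per_group=5, seed=0)
        cohort = cohort.drop(cohort[cohort.group == "healthy"].index[1:])
        with pytest.raises(CohortValidationError, match="healthy"):
            evaluate_cohort(cohort)

    def test_summary_contains_key_statistics(self):
        cohort = simulate_vitality_cohort(d=1.0, n_per_group=20, seed=5)
        res = ScreeningModel(cohort).fit()
        text = res.summary()
        assert "AUC" in text and "Cohen's d" in text and "Tukey-Kramer" in text
        assert f"{res.auc:.3f}" in text
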