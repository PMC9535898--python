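import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from multimut import (
    classify_mm,
    cox_fit,
    expression_by_mm,
    group_compare,
    km_estimate,
    log10_transform,
    logrank_test,
)


def hand_logrank_two_groups(t1, e1, t2, e2):
    """Observed-minus-expected log-rank chi-square computed from first
    principles (hand-table style), independent of the implementation."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O = E = V = 0.0
    for t in event_times:
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        d1 = np.sum((t1 == t) & (e1 == 1))
        d2 = np.sum((t2 == t) & (e2 == 1))
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def score_statistic_binary(group, times, events):
    """Cox partial-likelihood score test at beta = 0 for a binary covariate
    (Breslow ties); classically identical to the log-rank statistic."""
    group, times, events = map(np.asarray, (group, times, events))
    U = I = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        d = np.sum((times == t) & (events == 1))
        d_exposed = np.sum((times == t) & (events == 1) & (group == 1))
        p = group[at_risk].mean()
        U += d_exposed - d * p
        I += d * p * (1 - p)
    return U**2 / I


class TestKaplanMeier:
    def test_distinct_events_closed_form(self):
        fit = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert np.allclose(fit.survival, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert fit.median_time == 3

    def test_all_censored_flat_curve(self):
        fit = km_estimate([3, 5, 8], [0, 0, 0])
        assert np.allclose(fit.survival, 1.0)
        assert fit.median_time is None

    def test_hand_table(self):
        # times 1, 2, 2, 3, 4+; events 1, 1, 0, 1, 0
        # t=1: S = 4/5 = 0.8; t=2: one death of 4 at risk -> 0.6
        # t=3: one death of 2 at risk -> 0.3; t=4: censored, S stays 0.3
        fit = km_estimate([1, 2, 2, 3, 4], [1, 1, 0, 1, 0])
        table = dict(zip(fit.times, fit.survival))
        assert table[1.0] == pytest.approx(0.8)
        assert table[2.0] == pytest.approx(0.6)
        assert table[3.0] == pytest.approx(0.3)
        assert table[4.0] == pytest.approx(0.3)
        assert fit.median_time == 3

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=40).round(2)
        fit = km_estimate(times, np.ones_like(times, dtype=int))
        for t, s in zip(fit.times, fit.survival):
            assert s == pytest.approx(np.mean(times > t))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        g = ([5, 10, 15, 20], [1, 1, 0, 1])
        statistic, p = logrank_test([g, g])
        assert statistic == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_example(self):
        t1, e1 = [1.0, 4.0, 6.0], [1, 1, 0]
        t2, e2 = [2.0, 5.0, 7.0], [1, 0, 1]
        statistic, _ = logrank_test([(t1, e1), (t2, e2)])
        assert statistic == pytest.approx(hand_logrank_two_groups(t1, e1, t2, e2))

    def test_matches_hand_computation_on_random_data(self, rng):
        for _ in range(10):
            t1 = rng.exponential(10, size=12).round(1)
            t2 = rng.exponential(14, size=15).round(1)
            e1 = rng.integers(0, 2, size=12)
            e2 = rng.integers(0, 2, size=15)
            if e1.sum() + e2.sum() == 0:
                continue
            statistic, _ = logrank_test([(t1, e1), (t2, e2)])
            assert statistic == pytest.approx(
                hand_logrank_two_groups(t1, e1, t2, e2), rel=1e-9
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="zero subjects"):
            logrank_test([([1, 2], [1, 1]), ([], [])])


class TestCox:
    def test_constant_covariate_rejected(self):
        design = pd.DataFrame({"x": np.ones(30)})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(design, np.arange(1, 31), np.ones(30, dtype=int))

    def test_two_group_exponential_recovery(self):
        rng = np.random.default_rng(12)
        n = 2000
        group = rng.integers(0, 2, size=n)
        times = rng.exponential(1.0 / (0.05 * 2.0**group))
        fit = cox_fit(
            pd.DataFrame({"group": group}), times, np.ones(n, dtype=int)
        )
        coef = fit["group"]
        assert 1.8 <= coef.hazard_ratio <= 2.2
        assert coef.ci_low <= coef.hazard_ratio <= coef.ci_high

    def test_breslow_ties_option(self):
        rng = np.random.default_rng(4)
        n = 200
        group = rng.integers(0, 2, size=n)
        times = np.ceil(rng.exponential(10.0 / (1 + group)))  # heavy ties
        events = np.ones(n, dtype=int)
        efron = cox_fit(pd.DataFrame({"g": group}), times, events, ties="efron")
        breslow = cox_fit(pd.DataFrame({"g": group}), times, events, ties="breslow")
        assert efron.ties == "efron" and breslow.ties == "breslow"
        # both should find the same direction of effect
        assert (efron["g"].hazard_ratio > 1) == (breslow["g"].hazard_ratio > 1)

    def test_score_test_equals_logrank(self, rng):
        """Classical equivalence: the partial-likelihood score test at beta=0
        for a binary covariate is the log-rank chi-square."""
        for _ in range(20):
            n = int(rng.integers(20, 60))
            group = rng.integers(0, 2, size=n)
            if group.sum() in (0, n):
                continue
            times = rng.exponential(10, size=n)  # continuous: no ties
            events = rng.integers(0, 2, size=n)
            if events.sum() < 2:
                continue
            statistic, _ = logrank_test(
                [
                    (times[group == 0], events[group == 0]),
                    (times[group == 1], events[group == 1]),
                ]
            )
            score = score_statistic_binary(group, times, events)
            assert statistic == pytest.approx(score, abs=1e-6)


class TestGroupCompare:
    def test_identical_samples_mann_whitney(self):
        g = list(range(15))
        cmp = group_compare([g, g], test="mann_whitney")
        assert cmp.p_raw >= 0.99

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = [[8, 2], [1, 9]]
        cmp = group_compare(table, test="fisher_exact")
        # enumeration oracle: sum of hypergeometric probabilities of all
        # tables at most as probable as the observed one
        M, n, N = 20, 10, 9  # total, row-1 sum, column-1 sum
        p_obs = hypergeom.pmf(8, M, n, N)
        p_enum = sum(
            hypergeom.pmf(k, M, n, N)
            for k in range(max(0, N - (M - n)), min(n, N) + 1)
            if hypergeom.pmf(k, M, n, N) <= p_obs * (1 + 1e-9)
        )
        assert cmp.p_raw == pytest.approx(p_enum, rel=1e-6)

    def test_bonferroni_caps_at_one(self):
        cmp = group_compare([[1, 2, 3, 7], [2, 3, 4, 9]], test="mann_whitney",
                            m_comparisons=30)
        assert cmp.p_adjusted == 1.0
        assert cmp.adjustment == "bonferroni"

    def test_bonferroni_multiplies(self):
        cmp = group_compare([[1, 2, 3, 9], [4, 5, 6, 10]], test="mann_whitney",
                            m_comparisons=3)
        assert cmp.p_adjusted == pytest.approx(min(1.0, cmp.p_raw * 3))

    def test_chi_square_no_continuity_correction(self):
        from scipy.stats import chi2_contingency

        table = [[20, 10], [5, 25]]
        cmp = group_compare(table, test="chi_square")
        expected = chi2_contingency(np.array(table), correction=False)
        assert cmp.statistic == pytest.approx(expected.statistic)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([[], [1, 2]], test="mann_whitney")

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            group_compare([[1], [2]], test="t_test")


class TestLog10:
    def test_values(self):
        assert list(log10_transform([100, 1])) == [2.0, 0.0]

    def test_non_positive_named(self):
        with pytest.raises(ValueError, match="index 1"):
            log10_transform([10, 0, 5])


class TestExpressionByMM:
    def _classification(self, n_wild=20, n_single=20, n_multiple=20):
        counts = {}
        samples = []
        for i in range(n_wild):
            samples.append(f"W{i}")
        for i in range(n_single):
            samples.append(f"S{i}")
            counts[(f"S{i}", "MUC16")] = 1
        for i in range(n_multiple):
            samples.append(f"M{i}")
            counts[(f"M{i}", "MUC16")] = 2
        return classify_mm(counts, samples), samples

    def test_complete_separation_significant(self, rng):
        cls, samples = self._classification()
        fc = {}
        for s in samples:
            base = float(rng.uniform(0.8, 1.2))
            fc[s] = base * 10 if s.startswith("M") else base
        results = expression_by_mm(fc, cls, "MUC16")
        assert results[("single", "multiple")].p_adjusted < 0.01

    def test_null_p_values_roughly_uniform(self):
        """Under exchangeable fold changes, the MM-vs-SM p-value should be
        approximately U(0,1) (KS test not rejected at alpha = 0.01)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(2)
        cls, samples = self._classification()
        pvals = []
        for _ in range(400):
            fc = {s: float(rng.lognormal(0, 0.5)) for s in samples}
            pvals.append(expression_by_mm(fc, cls, "MUC16")[("single", "multiple")].p_raw)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_class_untestable(self, rng):
        cls, samples = self._classification(n_multiple=0)
        fc = {s: float(rng.lognormal(0, 0.3)) for s in samples}
        results = expression_by_mm(fc, cls, "MUC16")
        cmp = results[("single", "multiple")]
        assert not cmp.testable and "untestable" in cmp.note

    def test_non_positive_fold_change_rejected(self):
        cls, samples = self._classification(2, 2, 2)
        with pytest.raises(ValueError, match="fold change"):
            expression_by_mm({samples[0]: 0.0}, cls, "MUC16")
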