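"""Group summaries, LS-means ANOVA, logistic LRT, ROC AUC."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from netarm import (logistic_group_test, ls_means_anova, roc_auc,
                    summarize_group)


class TestSummarizeGroup:
    def test_printed_control_log_cga_interval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=143)
        # rescale so the sample stats equal the printed ones exactly
        x = (x - x.mean()) / x.std(ddof=1) * 0.48 + 1.29
        s = summarize_group(x)
        assert round(s.ci_low, 2) == 1.21
        assert round(s.ci_high, 2) == 1.37
        assert s.display() == ": 1.29 (0.48) [1.21-1.37]"

    def test_constant_vector_collapses(self):
        s = summarize_group([2.0, 2.0, 2.0])
        assert s.ci_low == s.ci_high == 2.0

    def test_closed_form_n4(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4)
        x = (x - x.mean()) / x.std(ddof=1)  # mean 0, sd 1
        s = summarize_group(x)
        assert s.ci_low == pytest.approx(-1.959964 / 2, abs=1e-5)
        assert s.ci_high == pytest.approx(1.959964 / 2, abs=1e-5)

    def test_ci_width_shrinks_at_root_n_rate(self):
        rng = np.random.default_rng(2)
        widths = {}
        for n in (10**2, 10**4, 10**6):
            x = rng.normal(0.0, 2.0, size=n)
            s = summarize_group(x)
            widths[n] = s.ci_high - s.ci_low
        assert widths[10**4] / widths[10**2] == pytest.approx(0.1, rel=0.15)
        assert widths[10**6] / widths[10**4] == pytest.approx(0.1, rel=0.15)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            summarize_group([1.0])


class TestLsMeansAnova:
    def test_balanced_design_ls_means_equal_raw_means(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=60)
        g = ["PD", "SD"] * 30
        t = ["a", "a", "b", "b", "c", "c"] * 10
        res = ls_means_anova(y, g, t)
        for lev in ("PD", "SD"):
            raw = np.mean([v for v, gg in zip(y, g) if gg == lev])
            assert res.ls_means[lev][0] == pytest.approx(raw, abs=1e-10)

    def test_single_treatment_level_reduces_to_one_way(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=45)
        g = (["PD"] * 20 + ["SD"] * 25)
        res = ls_means_anova(y, g, ["only"] * 45)
        f, p = sps.f_oneway(y[:20], y[20:])
        assert res.f_stat == pytest.approx(f, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_recovers_group_difference_at_reported_cpe_parameters(self):
        # PD 3.32 (0.74) n=65 vs SD 2.96 (0.33) n=50: the mean LS-mean
        # difference over simulated cohorts recovers 0.36
        rng = np.random.default_rng(5)
        diffs = []
        for _ in range(2000):
            y = np.concatenate([rng.normal(3.32, 0.74, 65),
                                rng.normal(2.96, 0.33, 50)])
            g = ["PD"] * 65 + ["SD"] * 50
            t = rng.choice(["SSA", "SSA+surgery", "other"], size=115)
            res = ls_means_anova(y, g, list(t))
            diffs.append(res.difference("PD", "SD"))
        assert np.mean(diffs) == pytest.approx(0.36, abs=0.02)

    def test_group_p_value_uniform_under_null(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(800):
            y = rng.normal(size=60)
            g = list(rng.choice(["PD", "SD"], size=60))
            t = list(rng.choice(["a", "b"], size=60))
            if len(set(g)) < 2:
                continue
            pvals.append(ls_means_anova(y, g, t).p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_cell_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            ls_means_anova([1.0, 2.0, 3.0, 4.0], ["PD", "PD", "SD", "SD"],
                           ["a", "a", "b", "b"])


class TestLogisticGroupTest:
    def test_two_by_two_lrt_equals_g_test(self):
        outcome = ["PD"] * 30 + ["SD"] * 20 + ["PD"] * 10 + ["SD"] * 25
        pred = ["x"] * 50 + ["y"] * 35
        res = logistic_group_test(outcome, pred)
        table = np.array([[30, 20], [10, 25]])
        g, p, dof, _ = sps.chi2_contingency(table, correction=False,
                                            lambda_="log-likelihood")
        assert res.lr_stat == pytest.approx(g, rel=1e-6)
        assert res.p_value == pytest.approx(p, rel=1e-6)
        assert res.df == 1

    def test_degenerate_outcome_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = logistic_group_test(["PD", "PD"], ["a", "b"])
        assert res.separation

    def test_separation_flagged(self):
        with pytest.warns(UserWarning, match="separation"):
            res = logistic_group_test(["PD"] * 10 + ["SD"] * 10,
                                      ["a"] * 10 + ["b"] * 10)
        assert res.separation


class TestRocAuc:
    def test_perfect_and_random_and_swapped(self):
        assert roc_auc([1, 2, 3, 4], [False, False, True, True]) == 1.0
        assert roc_auc([1, 1, 1, 1], [False, True, False, True]) == 0.5
        assert roc_auc([1, 2, 3, 4], [False, True, False, True]) == 0.75

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])

    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            return
        base = roc_auc(s, labels)
        assert roc_auc(np.exp(s), labels) == pytest.approx(base, abs=1e-12)
        assert roc_auc(3 * s + 7, labels) == pytest.approx(base, abs=1e-12)
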