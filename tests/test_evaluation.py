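"""ROC/AUC machinery and descriptive group comparisons."""

import numpy as np
import pytest
from scipy.stats import kstest, mannwhitneyu

from fetalgp.evaluation import auc_ci, compare_groups, dr_at_fpr, roc


def _mw_auc(scores, labels):
    """Independent oracle: Mann-Whitney U / (n1*n0), ties counted half."""
    pos, neg = scores[labels], scores[~labels]
    u, _ = mannwhitneyu(pos, neg, alternative="two-sided")
    return u / (len(pos) * len(neg))


class TestRoc:
    def test_uninformative_marker(self):
        y = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        s = np.full(10, 2.0)
        assert roc(s, y).auc == pytest.approx(0.5)

    def test_perfect_marker(self):
        y = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        s = np.r_[np.ones(5), np.zeros(5)]
        summary = roc(s, y)
        assert summary.auc == pytest.approx(1.0)
        assert summary.dr_at_fpr5 == 100.0 and summary.dr_at_fpr10 == 100.0
        assert summary.ci_degenerate
        assert summary.auc_ci95 == (1.0, 1.0)

    def test_auc_equals_mann_whitney_u(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 51))
            y = np.zeros(n, dtype=bool)
            y[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = True
            # coarse grid forces ties between and within classes
            s = rng.integers(0, 8, size=n).astype(float)
            assert roc(s, y, with_ci=False).auc == pytest.approx(_mw_auc(s, y), abs=1e-12)

    def test_complement_symmetry_tie_free(self, rng):
        n = 60
        s = rng.permutation(n).astype(float)
        y = np.zeros(n, dtype=bool)
        y[rng.choice(n, 20, replace=False)] = True
        a1 = roc(s, y, with_ci=False).auc
        a2 = roc(-s, y, with_ci=False).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        n = 80
        s = rng.normal(size=n)
        y = rng.random(n) < 0.3
        if y.sum() in (0, n):
            pytest.skip("degenerate draw")
        a1 = roc(s, y, with_ci=False).auc
        a2 = roc(np.exp(2.0 * s) + 5.0, y, with_ci=False).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_lower_risk_direction_flips(self, rng):
        n = 50
        s = rng.permutation(n).astype(float)
        y = np.zeros(n, dtype=bool)
        y[rng.choice(n, 15, replace=False)] = True
        assert roc(s, y, with_ci=False).auc == pytest.approx(
            roc(-s, y, direction="lower_risk", with_ci=False).auc, abs=1e-12
        )

    def test_curve_endpoints_and_step_sizes(self, rng):
        n_pos, n_neg = 13, 29
        s = rng.permutation(n_pos + n_neg).astype(float)  # tie-free
        y = np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(bool)
        summary = roc(s, y, with_ci=False)
        fpr, tpr = summary.fpr, summary.tpr
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        # tie-free: every step is a multiple of 1/n_pos (vertical) or 1/n_neg
        steps_v = np.diff(tpr) * n_pos
        steps_h = np.diff(fpr) * n_neg
        assert np.allclose(steps_v, np.round(steps_v), atol=1e-9)
        assert np.allclose(steps_h, np.round(steps_h), atol=1e-9)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc(np.arange(5.0), np.ones(5, dtype=bool))


class TestAucCi:
    def test_small_class_rejected(self):
        y = np.r_[np.ones(1), np.zeros(9)].astype(bool)
        with pytest.raises(ValueError):
            auc_ci(np.arange(10.0), y)

    def test_coverage_under_null(self):
        """DeLong interval covers AUC=0.5 for exchangeable scores ~95% of the time."""
        rng = np.random.default_rng(11)
        n = 50
        y = np.r_[np.ones(n), np.zeros(n)].astype(bool)
        hits = 0
        for _ in range(1000):
            s = rng.normal(size=2 * n)
            lo, hi = auc_ci(s, y)
            hits += lo <= 0.5 <= hi
        assert 920 <= hits <= 980

    def test_narrower_with_larger_n(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (40, 160, 640):
            y = np.r_[np.ones(n), np.zeros(n)].astype(bool)
            s = np.r_[rng.normal(0.8, 1, n), rng.normal(0, 1, n)]
            lo, hi = auc_ci(s, y)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestDrAtFpr:
    def test_monotone_in_target(self, rng):
        n = 300
        s = rng.normal(size=n)
        y = rng.random(n) < 0.2
        s[y] += 1.0
        summary = roc(s, y, with_ci=False)
        assert summary.dr_at_fpr10 >= summary.dr_at_fpr5

    def test_chance_level_marker(self):
        rng = np.random.default_rng(5)
        n = 2000
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(bool)
        s = rng.normal(size=n)
        summary = roc(s, y, with_ci=False)
        assert summary.dr_at_fpr10 == pytest.approx(10.0, abs=4.0)
        assert summary.dr_at_fpr5 == pytest.approx(5.0, abs=3.0)

    def test_step_convention_does_not_exceed_target_fpr(self, rng):
        n = 97
        s = rng.normal(size=n)
        y = rng.random(n) < 0.3
        summary = roc(s, y, with_ci=False)
        for target in (0.05, 0.10):
            dr = dr_at_fpr(summary, target)
            # the achieving point must itself respect the FPR cap
            mask = summary.fpr <= target + 1e-12
            assert dr == pytest.approx(summary.tpr[mask].max() * 100)
        # interpolated variant is at least the step value at the same target
        assert dr_at_fpr(summary, 0.05, interpolate=True) >= dr_at_fpr(summary, 0.05) - 1e-9

    def test_invalid_target(self, rng):
        y = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        summary = roc(np.arange(10.0), y, with_ci=False)
        with pytest.raises(ValueError):
            dr_at_fpr(summary, 1.5)


class TestCompareGroups:
    def test_identical_proportions_give_zero_chi_square(self):
        import pandas as pd

        df = pd.DataFrame({"ifc": [0] * 20 + [1] * 20, "flag": ([0] * 10 + [1] * 10) * 2})
        (comp,) = compare_groups(df, categorical=["flag"])
        assert comp.statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.p_value == pytest.approx(1.0)

    def test_null_p_values_uniform(self):
        """Under label exchange the Mann-Whitney p is uniform on (0, 1)."""
        import pandas as pd

        rng = np.random.default_rng(8)
        pvals = []
        x = rng.normal(size=200)
        for _ in range(500):
            y = np.zeros(200, dtype=int)
            y[rng.choice(200, 30, replace=False)] = 1
            df = pd.DataFrame({"ifc": y, "x": x})
            (comp,) = compare_groups(df, continuous=["x"])
            pvals.append(comp.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_spec_shift_detected_in_default_cohort(self, assessed):
        comps = compare_groups(assessed, continuous=["mca_pi_mom"])
        assert comps[0].p_value < 0.05
        assert comps[0].test == "mann_whitney"

    def test_all_missing_variable_skipped_not_dropped(self, assessed):
        df = assessed.copy()
        df["ghost"] = np.nan
        comps = compare_groups(df, continuous=["ghost", "mca_pi_mom"])
        assert comps[0].test == "skipped"
        assert comps[1].test == "mann_whitney"

    def test_fisher_flag_on_small_cells(self, assessed):
        comps = compare_groups(assessed, categorical=["smoking"], fisher=True)
        assert comps[0].test == "fisher_exact"
        assert 0 < comps[0].p_value <= 1
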