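"""Task averaging, baseline deviations and the repeated-measures statistics."""

import numpy as np
import pytest
from scipy import stats

from netlearn.cohort import (
    AnovaResult,
    TaskMetrics,
    paired_t_test,
    pearson_correlation,
    relative_deviation,
    rm_anova_sphericity,
    run_cohort,
    task_mean,
)
from netlearn.exceptions import (
    DegenerateInputError,
    DegenerateStatisticError,
    IncompleteDesignError,
    ParameterError,
)
from netlearn.io import SubjectRecord
from netlearn.network import WindowMetrics


def wm(c, l, idx=0):
    return WindowMetrics(window_index=idx, clustering=c, path_length=l)


def tm(sid, task, c, l, n=1):
    return TaskMetrics(subject_id=sid, task=task, C_task=c, L_task=l, n_windows=n)


class TestTaskMean:
    def test_mean_of_windows(self):
        out = task_mean([wm(0.4, 2.0), wm(0.6, 3.0)], "S1", "L1")
        assert out.C_task == pytest.approx(0.5)
        assert out.L_task == pytest.approx(2.5)
        assert out.n_windows == 2

    def test_single_window_identity(self):
        out = task_mean([wm(0.37, 1.9)], "S1", "B")
        assert (out.C_task, out.L_task) == (0.37, 1.9)

    def test_eleven_windows_match_direct_sum(self, rng):
        cs = rng.uniform(0.2, 0.8, 11)
        ls = rng.uniform(1.5, 3.0, 11)
        out = task_mean([wm(c, l, i) for i, (c, l) in enumerate(zip(cs, ls))],
                        "S1", "L1")
        assert out.C_task == pytest.approx(cs.sum() / 11)
        assert out.L_task == pytest.approx(ls.sum() / 11)

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            task_mean([], "S1", "B")


class TestRelativeDeviation:
    @pytest.mark.parametrize("c_task,expected", [(0.5, 0.0), (0.525, 5.0)])
    def test_clustering_deviation(self, c_task, expected):
        d = relative_deviation(tm("S1", "L2", c_task, 2.0), tm("S1", "B", 0.5, 2.0))
        assert d.dC_pct == pytest.approx(expected)

    def test_path_length_shrink(self):
        d = relative_deviation(tm("S1", "L1", 0.5, 1.6), tm("S1", "B", 0.5, 2.0))
        assert d.dL_pct == pytest.approx(-20.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(DegenerateInputError):
            relative_deviation(tm("S1", "L1", 0.5, 2.0), tm("S1", "B", 0.0, 2.0))

    def test_scale_invariance(self, rng):
        """Multiplying a subject's C in all tasks leaves dC% unchanged."""
        c_b, c_t = 0.41, 0.47
        base = relative_deviation(tm("S", "L2", c_t, 2), tm("S", "B", c_b, 2))
        for a in (0.1, 3.0, 17.0):
            scaled = relative_deviation(tm("S", "L2", a * c_t, 2),
                                        tm("S", "B", a * c_b, 2))
            assert scaled.dC_pct == pytest.approx(base.dC_pct)


class TestPairedT:
    def test_identical_samples(self):
        t, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_sign_flip_negates_t(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        t1, p1 = paired_t_test(x, y)
        t2, p2 = paired_t_test(y, x)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_six_pair_textbook_formula(self):
        x = np.array([10.2, 9.1, 11.3, 8.7, 10.9, 9.8])
        y = np.array([9.5, 9.3, 10.1, 8.2, 10.1, 9.0])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        p_hand = 2 * stats.t.sf(abs(t_hand), 5)
        t, p = paired_t_test(x, y)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert p == pytest.approx(p_hand, abs=1e-12)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(8.0)
        assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_eight_point_formula(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r_hand = (np.mean((x - x.mean()) * (y - y.mean()))
                  / (x.std() * y.std()))
        r, p = pearson_correlation(x, y)
        assert r == pytest.approx(r_hand, abs=1e-12)
        t = r * np.sqrt(6 / (1 - r ** 2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 6), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRmAnova:
    def test_toy_matrix_matches_sums_of_squares_oracle(self):
        """F from explicit SS decomposition on a fixed 5-subject design."""
        y = np.array([[0.50, 0.52, 0.55],
                      [0.44, 0.43, 0.49],
                      [0.61, 0.63, 0.62],
                      [0.38, 0.41, 0.45],
                      [0.55, 0.54, 0.60]])
        n, m = y.shape
        grand = y.mean()
        ss_cond = n * sum((y[:, j].mean() - grand) ** 2 for j in range(m))
        ss_err = sum((y[i, j] - y[i].mean() - y[:, j].mean() + grand) ** 2
                     for i in range(n) for j in range(m))
        f_hand = (ss_cond / (m - 1)) / (ss_err / ((n - 1) * (m - 1)))
        res = rm_anova_sphericity(y)
        assert res.F == pytest.approx(f_hand, abs=1e-12)
        assert res.p_uncorrected == pytest.approx(
            stats.f.sf(f_hand, 2, 8), abs=1e-12)

    def test_epsilon_bounds_for_three_conditions(self, rng):
        for _ in range(10):
            y = rng.normal(size=(8, 3))
            y[:, 2] = y[:, 1] + 1e-9 * rng.normal(size=8)  # near-degenerate pair
            res = rm_anova_sphericity(y)
            assert 0.5 - 1e-12 <= res.epsilon_gg <= 1.0
            assert res.epsilon_gg <= res.epsilon_hf + 1e-12

    def test_two_conditions_reduce_to_paired_t(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(0, 0.5, size=12)
        t, p_t = paired_t_test(x, y)
        res = rm_anova_sphericity(np.column_stack([x, y]))
        assert res.F == pytest.approx(t ** 2, rel=1e-10)
        assert res.p_uncorrected == pytest.approx(p_t, abs=1e-12)
        assert res.epsilon_gg == 1.0

    def test_matches_pingouin(self, rng):
        """Cross-check F, uncorrected p and GG correction against pingouin."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        y = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        df = pd.DataFrame(y, columns=["B", "L1", "L2"])
        df["subject"] = range(10)
        long = df.melt(id_vars="subject", var_name="cond", value_name="y")
        table = pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                            correction=True)
        res = rm_anova_sphericity(y)
        assert res.F == pytest.approx(float(table["F"].iloc[0]), rel=1e-9)
        assert res.p_uncorrected == pytest.approx(
            float(table["p_unc"].iloc[0]), abs=1e-12)
        assert res.epsilon_gg == pytest.approx(float(table["eps"].iloc[0]), rel=1e-6)
        assert res.p_gg == pytest.approx(float(table["p_GG_corr"].iloc[0]), abs=1e-9)

    def test_flat_subjects_report_no_effect(self):
        y = np.tile(np.array([[0.4], [0.5], [0.6]]), (1, 3))
        res = rm_anova_sphericity(y)
        assert res.F == 0.0 and res.p_uncorrected == 1.0

    def test_missing_cells_rejected(self):
        y = np.ones((4, 3))
        y[1, 2] = np.nan
        with pytest.raises(IncompleteDesignError):
            rm_anova_sphericity(y)

    def test_primary_p_rule(self):
        res = AnovaResult(F=1.0, df_num=2, df_den=8, p_uncorrected=0.4,
                          epsilon_gg=0.6, epsilon_hf=0.7, p_gg=0.5, p_hf=0.45)
        assert res.p_primary == 0.5
        res.epsilon_gg = 0.9
        assert res.p_primary == 0.4


class TestRunCohort:
    @staticmethod
    def _subjects(n):
        return [SubjectRecord(f"S{i}", "control" if i % 2 else "patient",
                              5 + i % 5, 7 + i % 5) for i in range(n)]

    @staticmethod
    def _metrics(n, rng, effect=0.0):
        mets = []
        for i in range(n):
            base_c = 0.4 + 0.02 * i
            base_l = 2.0 + 0.05 * i
            for task in ("B", "L1", "L2"):
                bump = effect if task == "L2" else 0.0
                mets.append(tm(f"S{i}", task,
                               base_c * (1 + bump) + rng.normal(0, 0.002),
                               base_l + rng.normal(0, 0.01), n=11))
        return mets

    def test_flat_cohort_has_zero_deviations(self):
        mets = []
        for i in range(5):
            for task in ("B", "L1", "L2"):
                mets.append(tm(f"S{i}", task, 0.4 + 0.01 * i, 2.0))
        res = run_cohort(mets, self._subjects(5))
        for task in ("L1", "L2"):
            assert res.deviation_summary[task]["dC_pct"]["mean"] == pytest.approx(0)
        assert res.anova_C.p_uncorrected == pytest.approx(1.0)
        assert res.pairwise_C == {}  # omnibus not significant -> no pairwise tests

    def test_injected_effect_detected(self, rng):
        res = run_cohort(self._metrics(12, rng, effect=0.08), self._subjects(12))
        assert res.deviation_summary["L2"]["dC_pct"]["mean"] > \
            res.deviation_summary["L1"]["dC_pct"]["mean"]
        assert res.anova_C.p_primary < 0.05
        assert "B_vs_L2" in res.pairwise_C

    def test_incomplete_subject_excluded_with_warning(self, rng, caplog):
        mets = self._metrics(6, rng)
        mets = [m for m in mets if not (m.subject_id == "S3" and m.task == "L2")]
        with caplog.at_level("WARNING", logger="netlearn.cohort"):
            res = run_cohort(mets, self._subjects(6))
        assert res.n_subjects == 5
        assert res.excluded_subjects == ["S3"]
        assert "S3" in caplog.text

    def test_correlation_pairs_reported(self, rng):
        res = run_cohort(self._metrics(10, rng), self._subjects(10))
        assert set(res.correlations) == {
            "dC_L1~recall_incidental", "dC_L2~recall_intentional",
            "dL_L1~recall_incidental", "dL_L2~recall_intentional",
            "dC_L2~recall_incidental"}
        for v in res.correlations.values():
            assert -1 <= v["r"] <= 1 and 0 <= v["p"] <= 1 and v["n"] == 10

    def test_bad_alpha_rejected(self, rng):
        with pytest.raises(ParameterError):
            run_cohort(self._metrics(5, rng), self._subjects(5), alpha=1.5)
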