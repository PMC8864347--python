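import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ticwalk import (InsufficientDataError, condition_summary, delta_analysis,
                     interrater_agreement, rm_anova)

from conftest import SUITE_SEED


def _table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "visit", "condition",
                                       "rater_id", "D_f", "fit_r2", "n_tics",
                                       "degenerate", "severity"])


def _baseline_row(subj, visit, d_f, severity):
    return (subj, visit, "baseline", "r1", d_f, 0.99, 10, False, severity)


class TestDeltaAnalysis:
    def test_exact_negative_proportionality_gives_minus_one(self):
        rows = []
        for i, dsev in enumerate([-10.0, -2.0, 4.0, 9.0]):
            rows.append(_baseline_row(f"s{i}", "screening", 1.5, 20.0))
            rows.append(_baseline_row(f"s{i}", "twelve_month",
                                      1.5 - 0.02 * dsev, 20.0 + dsev))
        res = delta_analysis(_table(rows))
        assert res.r == pytest.approx(-1.0)
        assert res.n == 4

    def test_constant_severity_change_flagged(self):
        rows = []
        for i in range(4):
            rows.append(_baseline_row(f"s{i}", "screening", 1.0 + 0.1 * i, 20.0))
            rows.append(_baseline_row(f"s{i}", "twelve_month",
                                      1.2 + 0.05 * i, 25.0))
        res = delta_analysis(_table(rows))
        assert np.isnan(res.r)
        assert res.flag is not None

    def test_too_few_subjects_rejected(self):
        rows = [_baseline_row("a", "screening", 1.0, 10.0),
                _baseline_row("a", "twelve_month", 1.1, 12.0),
                _baseline_row("b", "screening", 1.2, 14.0),
                _baseline_row("b", "twelve_month", 1.0, 9.0)]
        with pytest.raises(InsufficientDataError):
            delta_analysis(_table(rows))

    def test_degenerate_sessions_excluded(self):
        rows = []
        for i, dsev in enumerate([-5.0, 0.0, 5.0]):
            rows.append(_baseline_row(f"s{i}", "screening", 1.5, 20.0))
            rows.append(_baseline_row(f"s{i}", "twelve_month",
                                      1.5 - 0.01 * dsev, 20.0 + dsev))
        # a fourth subject with a degenerate fit must not enter the analysis
        rows.append(("s9", "screening", "baseline", "r1", 99.0, 0.1, 0,
                     True, 20.0))
        rows.append(("s9", "twelve_month", "baseline", "r1", -99.0, 0.1, 0,
                     True, 40.0))
        res = delta_analysis(_table(rows))
        assert res.n == 3


class TestConditionSummary:
    def test_identical_values_zero_width_interval(self):
        rows = [(f"s{i}", "screening", "DRO", "r1", 1.4, 0.99, 5, False,
                 np.nan) for i in range(5)]
        out = condition_summary(_table(rows))
        row = out.iloc[0]
        assert row["mean_D_f"] == pytest.approx(1.4)
        assert row["ci_lo"] == pytest.approx(1.4)
        assert row["ci_hi"] == pytest.approx(1.4)

    def test_two_values_closed_form(self):
        a, b = 1.2, 1.8
        rows = [("s0", "screening", "verbal", "r1", a, 0.99, 5, False, np.nan),
                ("s1", "screening", "verbal", "r1", b, 0.99, 5, False, np.nan)]
        out = condition_summary(_table(rows))
        row = out.iloc[0]
        mean = (a + b) / 2
        half = stats.t.ppf(0.975, 1) * np.std([a, b], ddof=1) / np.sqrt(2)
        assert row["mean_D_f"] == pytest.approx(mean)
        assert row["ci_lo"] == pytest.approx(mean - half)
        assert row["ci_hi"] == pytest.approx(mean + half)

    def test_singleton_flagged(self):
        rows = [("s0", "screening", "NCR", "r1", 1.5, 0.99, 5, False, np.nan)]
        out = condition_summary(_table(rows))
        assert out.iloc[0]["flag"] == "singleton"
        assert np.isnan(out.iloc[0]["ci_lo"])


def _anova_table(values_by_subject):
    rows = []
    for subj, cond_vals in values_by_subject.items():
        for cond, val in cond_vals.items():
            rows.append((subj, "screening", cond, "r1", val, 0.99, 5, False,
                         np.nan))
    return _table(rows)


def _manual_rm_f(values):
    """Brute-force within-subjects sums of squares on a subjects x conds array."""
    arr = np.asarray(values, float)
    n, k = arr.shape
    grand = arr.mean()
    ss_cond = n * np.sum((arr.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((arr.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((arr - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    return (ss_cond / df1) / (ss_err / df2), df1, df2


class TestRmAnova:
    def test_matches_manual_sums_of_squares(self):
        vals = np.array([[1.2, 1.5], [1.0, 1.6], [1.3, 1.4]])
        table = _anova_table({f"s{i}": {"baseline": vals[i, 0],
                                        "DRO": vals[i, 1]}
                              for i in range(3)})
        res = rm_anova(table)
        f_ref, df1, df2 = _manual_rm_f(vals)
        assert res.F == pytest.approx(f_ref, rel=1e-10)
        assert (res.df_num, res.df_den) == (df1, df2)

    def test_equal_condition_means_give_zero_f(self):
        table = _anova_table({"s0": {"baseline": 1.0, "DRO": 2.0},
                              "s1": {"baseline": 2.0, "DRO": 1.0}})
        res = rm_anova(table)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_per_subject_shift(self):
        rng = np.random.default_rng(SUITE_SEED)
        vals = rng.normal(1.5, 0.2, size=(6, 3))
        conds = ["baseline", "verbal", "DRO"]
        base = _anova_table({f"s{i}": dict(zip(conds, vals[i]))
                             for i in range(6)})
        shifted_vals = vals + rng.normal(0, 1, size=(6, 1))
        shifted = _anova_table({f"s{i}": dict(zip(conds, shifted_vals[i]))
                                for i in range(6)})
        assert rm_anova(base).F == pytest.approx(rm_anova(shifted).F,
                                                 rel=1e-9)

    def test_incomplete_subject_dropped_with_warning(self):
        table = _anova_table({"s0": {"baseline": 1.0, "DRO": 1.5},
                              "s1": {"baseline": 1.2, "DRO": 1.1},
                              "s2": {"baseline": 1.3}})
        with pytest.warns(UserWarning, match="incomplete"):
            res = rm_anova(table)
        assert res.n_subjects == 2
        assert res.n_dropped_subjects == 1

    def test_insufficient_data_rejected(self):
        table = _anova_table({"s0": {"baseline": 1.0, "DRO": 1.5}})
        with pytest.raises(InsufficientDataError):
            rm_anova(table)

    def test_parametric_p_close_to_permutation_p(self):
        rng = np.random.default_rng(SUITE_SEED)
        n, k = 10, 3
        vals = rng.normal(1.5, 0.15, size=(n, k)) + [0.0, 0.05, 0.10]
        conds = ["baseline", "verbal", "DRO"]
        table = _anova_table({f"s{i}": dict(zip(conds, vals[i]))
                              for i in range(n)})
        f_obs = rm_anova(table).F
        p_param = rm_anova(table).p
        exceed = 0
        n_perm = 500
        for _ in range(n_perm):
            perm = np.array([row[rng.permutation(k)] for row in vals])
            f_perm, _, _ = _manual_rm_f(perm)
            exceed += f_perm >= f_obs
        p_perm = exceed / n_perm
        assert abs(p_perm - p_param) < 0.12


class TestInterrater:
    def _tables(self, d1, d2):
        rows1 = [(f"s{i}", "screening", "baseline", "r1", v, 0.99, 5, False,
                  np.nan) for i, v in enumerate(d1)]
        rows2 = [(f"s{i}", "screening", "baseline", "r2", v, 0.99, 5, False,
                  np.nan) for i, v in enumerate(d2)]
        return _table(rows1), _table(rows2)

    def test_identical_tables_perfect_agreement(self):
        d = [1.1, 1.3, 1.8, 1.5]
        r, p, n = interrater_agreement(*self._tables(d, d))
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(SUITE_SEED)
        r, _, _ = interrater_agreement(
            *self._tables(rng.normal(1.5, 0.2, 100),
                          rng.normal(1.5, 0.2, 100)))
        assert abs(r) < 0.3

    def test_no_matches_rejected(self):
        t1, t2 = self._tables([1.0, 1.1, 1.2], [1.0, 1.1, 1.2])
        t2["visit"] = "twelve_month"
        with pytest.raises(InsufficientDataError):
            interrater_agreement(t1, t2)
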