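"""Repeated-measures statistics against independent oracles.

The brute-force oracle computes the within-subject sums of squares with
explicit loops and the Greenhouse–Geisser epsilon from the *eigenvalues* of the
double-centered covariance (the implementation uses the trace form), so the two
routes share no code.  pingouin provides a third, external cross-check.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluoroquant.longitudinal import (
    LongitudinalTable,
    detectability_tally,
    percent_remaining,
    rm_anova,
    tukey_posthoc,
)


def oracle_rm_anova(x: np.ndarray):
    """Loop-based sums of squares + eigen-decomposition epsilon."""
    n, k = x.shape
    grand = x.mean()
    ss_time = 0.0
    for j in range(k):
        ss_time += n * (x[:, j].mean() - grand) ** 2
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
    f = (ss_time / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    s = np.cov(x, rowvar=False)
    dc = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
    lam = np.linalg.eigvalsh(dc)
    eps = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
    eps = min(1.0, max(1.0 / (k - 1), eps))
    df1, df2 = eps * (k - 1), eps * (k - 1) * (n - 1)
    return f, eps, df1, df2, stats.f.sf(f, df1, df2)


def _table(x: np.ndarray) -> LongitudinalTable:
    cols = [f"day{j}" for j in range(x.shape[1])]
    return LongitudinalTable(pd.DataFrame(x, columns=cols))


class TestRmAnova:
    def test_no_time_effect_gives_zero_f(self):
        # identical columns plus per-subject offsets: MS_time = 0
        offsets = np.array([[1.0], [5.0], [9.0], [2.0]])
        x = np.tile(offsets, (1, 4))
        res = rm_anova(_table(x))
        assert res.F == 0.0
        assert res.p == 1.0

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(3, 6))
            x = rng.normal(500.0, 20.0, (n, k)) + rng.normal(0, 50, (n, 1))
            res = rm_anova(_table(x))
            f, eps, df1, df2, p = oracle_rm_anova(x)
            assert res.F == pytest.approx(f, abs=1e-8)
            assert res.epsilon == pytest.approx(eps, abs=1e-8)
            assert res.df1 == pytest.approx(df1, abs=1e-8)
            assert res.df2 == pytest.approx(df2, abs=1e-8)
            assert res.p == pytest.approx(p, abs=1e-8)
            assert 1.0 / (k - 1) - 1e-12 <= res.epsilon <= 1.0 + 1e-12
            # fractional-df structure: df2/df1 reveals the complete-case n
            assert res.df2 / res.df1 == pytest.approx(n - 1, rel=1e-12)

    def test_df_ratio_identifies_five_subjects(self, rng):
        # a printed F(1.703, 6.812) has 6.812/1.703 = 4, i.e. n = 5 complete cases
        x = rng.normal(100.0, 10.0, (5, 4))
        res = rm_anova(_table(x))
        assert res.df2 / res.df1 == pytest.approx(4.0, rel=1e-12)

    def test_epsilon_is_one_under_compound_symmetry(self):
        # all 6 permutations of (0,1,2) make the columns exchangeable, so the
        # sample covariance is exactly compound-symmetric
        from itertools import permutations

        x = np.array(list(permutations([0.0, 1.0, 2.0])))
        res = rm_anova(_table(x))
        assert res.epsilon == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_per_subject_constants(self, rng):
        x = rng.normal(1000.0, 3.0, (6, 4))
        shifted = x + rng.uniform(0, 100, (6, 1))
        a, b = rm_anova(_table(x)), rm_anova(_table(shifted))
        assert b.F == pytest.approx(a.F, rel=1e-9)
        assert b.epsilon == pytest.approx(a.epsilon, rel=1e-9)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for seed in range(3):
            r = np.random.default_rng(seed)
            x = r.normal(500, 10, (6, 4)) + r.normal(0, 15, (6, 1))
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(6), 4),
                "time": np.tile(np.arange(4), 6),
                "y": x.ravel(),
            })
            ref = pg.rm_anova(data=long, dv="y", within="time", subject="subject",
                              correction=True)
            res = rm_anova(_table(x))
            assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
            assert res.epsilon == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)
            assert res.p == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            rm_anova(_table(np.array([[1.0, 2.0, 3.0]])))

    def test_missing_timepoints_drop_to_complete_cases(self, rng):
        x = rng.normal(100.0, 5.0, (6, 4))
        x[0, 2] = np.nan
        with pytest.warns(UserWarning, match="excluding 1 subject"):
            res = rm_anova(_table(x))
        assert res.n_subjects == 5


class TestTukey:
    def test_identical_columns_all_nonsignificant(self):
        x = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        res = tukey_posthoc(_table(x))
        assert (res.table["p_adj"] == 1.0).all()

    def test_pair_count(self, rng):
        res = tukey_posthoc(_table(rng.normal(100.0, 5.0, (5, 4))))
        assert len(res.table) == 6  # k(k-1)/2 with k = 4

    def test_huge_separation_is_significant(self, rng):
        # two of the timepoints differ by ~100 pooled SDs
        n = 6
        base = rng.normal(1000.0, 1.0, (n, 3))
        base[:, 2] += 100.0
        res = tukey_posthoc(_table(base))
        pair = res.table[(res.table.level_a == "day0") & (res.table.level_b == "day2")]
        assert float(pair["p_adj"].iloc[0]) < 1e-4

    def test_two_level_case_reduces_to_paired_t(self, rng):
        # with k = 2 the studentized range q equals sqrt(2)*|t| and the
        # adjusted p equals the two-sided paired t-test p
        x = rng.normal(10, 2, (8, 2))
        res = tukey_posthoc(_table(x))
        t = stats.ttest_rel(x[:, 1], x[:, 0])
        assert float(res.table["p_adj"].iloc[0]) == pytest.approx(t.pvalue, rel=1e-6)
        assert float(res.table["q"].iloc[0]) == pytest.approx(
            np.sqrt(2) * abs(t.statistic), rel=1e-9)


class TestSummaries:
    def test_percent_remaining_ratios(self):
        x = np.array([[2e6, 2e5, 0.0], [1e6, 1e6, 5e5]])
        pct = percent_remaining(_table(x), "day0")
        assert pct.iloc[0].tolist() == pytest.approx([100.0, 10.0, 0.0])
        assert pct.iloc[1].tolist() == pytest.approx([100.0, 100.0, 50.0])

    def test_zero_baseline_subject_excluded(self):
        x = np.array([[0.0, 1.0], [2.0, 1.0]])
        with pytest.warns(UserWarning, match="baseline"):
            pct = percent_remaining(_table(x), "day0")
        assert len(pct) == 1

    def test_missing_baseline_timepoint_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            percent_remaining(_table(np.ones((3, 3))), "day99")

    def test_detectability_tally_counts(self):
        flags = pd.DataFrame(
            [[True, True], [True, False], [True, False], [True, False],
             [True, True], [True, False], [True, False]],
            columns=["day0", "day16"],
        )
        tally = detectability_tally(flags)
        assert tally.loc[tally.timepoint == "day0", "display"].item() == "7/7"
        assert tally.loc[tally.timepoint == "day16", "display"].item() == "2/7"
        assert tally.loc[tally.timepoint == "day16", "fraction"].item() == pytest.approx(2 / 7)

    def test_all_false_tally(self):
        flags = pd.DataFrame([[False], [False], [False]], columns=["day0"])
        assert detectability_tally(flags)["display"].item() == "0/3"


class TestTableValidation:
    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError, match="2 timepoints"):
            _table(np.ones((3, 1)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            _table(np.array([[1.0, -2.0], [3.0, 4.0]]))

    def test_long_format_round_trip(self):
        long = pd.DataFrame({
            "subject": ["a", "a", "b", "b"],
            "timepoint": ["day0", "day3", "day0", "day3"],
            "cell_count": [4.0, 2.0, 8.0, 6.0],
        })
        table = LongitudinalTable.from_long(long, timepoint_order=["day0", "day3"])
        assert table.counts.loc["b", "day3"] == 6.0
        assert table.timepoints == ["day0", "day3"]
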