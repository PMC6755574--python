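import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qsarlab import (
    blocked_anova,
    make_performance_table,
    mcs_matrix,
    n_pairs,
    tukey_kramer,
)
from qsarlab.measures import PerformanceTable


def statsmodels_anova(df: pd.DataFrame) -> pd.DataFrame:
    """Independent oracle: least-squares additive fit via statsmodels."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    long = df.stack().reset_index()
    long.columns = ["split", "combo", "y"]
    model = ols("y ~ C(split) + C(combo)", data=long).fit()
    return sm.stats.anova_lm(model, typ=2)


def _table(values, **kw):
    df = pd.DataFrame(np.asarray(values, float))
    df.columns = [f"c{j}" for j in range(df.shape[1])]
    return PerformanceTable(values=df, measure=kw.pop("measure", "auc"),
                            larger_is_better=kw.pop("larger_is_better", True))


class TestNPairs:
    @pytest.mark.parametrize("c, expected", [(18, 153), (2, 1), (5, 10)])
    def test_choose_two(self, c, expected):
        assert n_pairs(c) == expected

    def test_rejects_single_combo(self):
        with pytest.raises(ValueError):
            n_pairs(1)


class TestBlockedAnova:
    def test_hand_computed_decomposition(self):
        a = blocked_anova(_table([[1, 3], [2, 4]]))
        assert a.ss_split == pytest.approx(1.0)
        assert a.ss_combo == pytest.approx(4.0)
        assert a.ss_error == pytest.approx(0.0, abs=1e-12)
        assert a.ss_total == pytest.approx(5.0)

    def test_pure_interaction_lands_in_error(self):
        a = blocked_anova(_table([[1, 2], [2, 1]]))
        assert a.ss_split == pytest.approx(0.0, abs=1e-12)
        assert a.ss_combo == pytest.approx(0.0, abs=1e-12)
        assert a.ss_error == pytest.approx(1.0)
        assert a.df_error == 1

    def test_location_invariance(self, rng):
        Y = rng.standard_normal((3, 5))
        a = blocked_anova(_table(Y))
        b = blocked_anova(_table(Y + 17.3))
        for attr in ("ss_split", "ss_combo", "ss_error", "p_split", "p_combo"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr))

    def test_matches_statsmodels_least_squares(self, rng):
        table = make_performance_table(s=3, c=6, sigma=0.5, seed=42)
        ours = blocked_anova(table)
        oracle = statsmodels_anova(table.values)
        assert ours.ss_split == pytest.approx(oracle.loc["C(split)", "sum_sq"],
                                              rel=1e-8)
        assert ours.ss_combo == pytest.approx(oracle.loc["C(combo)", "sum_sq"],
                                              rel=1e-8)
        assert ours.ss_error == pytest.approx(oracle.loc["Residual", "sum_sq"],
                                              rel=1e-8)
        assert ours.p_combo == pytest.approx(oracle.loc["C(combo)", "PR(>F)"],
                                             rel=1e-6)
        assert ours.p_split == pytest.approx(oracle.loc["C(split)", "PR(>F)"],
                                             rel=1e-6)

    def test_incomplete_table_refused(self):
        t = _table([[1, np.nan], [2, 3]])
        with pytest.raises(ValueError, match="drop incomplete"):
            blocked_anova(t)

    def test_single_split_refused(self):
        with pytest.raises(ValueError):
            blocked_anova(_table([[1, 2, 3]]))


class TestTukeyKramer:
    def test_identical_columns_null_pair(self):
        Y = np.array([[1.0, 1.0, 2.0], [2.0, 2.0, 4.0], [3.0, 3.0, 5.0]])
        comp = tukey_kramer(_table(Y))
        row = comp.pairs[(comp.pairs.combo_a == "c0")
                         & (comp.pairs.combo_b == "c1")].iloc[0]
        assert row["diff"] == pytest.approx(0.0)
        assert row.p_adjusted == pytest.approx(1.0)

    def test_two_groups_equal_paired_t_test(self, rng):
        """With c=2 the studentized range reduces to sqrt(2)|t|, so the
        adjusted p equals the two-sided paired t-test on the differences."""
        for seed in range(5):
            Y = np.random.default_rng(seed).standard_normal((6, 2))
            comp = tukey_kramer(_table(Y))
            t_p = stats.ttest_rel(Y[:, 0], Y[:, 1]).pvalue
            assert comp.pairs.p_adjusted.iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_eighteen_combos_give_153_pairs(self):
        comp = tukey_kramer(make_performance_table(s=3, c=18, seed=1))
        assert comp.n_pairs == 153

    def test_adjusted_never_below_unadjusted_t(self, rng):
        for seed in range(20):
            table = make_performance_table(
                s=3, c=int(np.random.default_rng(seed).integers(3, 7)),
                sigma=0.3, seed=seed)
            comp = tukey_kramer(table)
            a = comp.anova
            for _, row in comp.pairs.iterrows():
                t = abs(row["diff"]) / np.sqrt(2 * a.ms_error / table.n_splits)
                p_t = 2 * stats.t.sf(t, a.df_error)
                assert row.p_adjusted >= p_t - 1e-9

    def test_scale_invariance_of_p_values(self, rng):
        Y = rng.standard_normal((3, 5)) + 2
        p1 = tukey_kramer(_table(Y)).pairs.p_adjusted.to_numpy()
        p2 = tukey_kramer(_table(4.2 * Y)).pairs.p_adjusted.to_numpy()
        np.testing.assert_allclose(p1, p2, rtol=1e-9)

    def test_degenerate_zero_error(self):
        # perfectly additive table: MS_error = 0
        Y = np.array([[1.0, 2.0], [2.0, 3.0]])
        with pytest.warns(UserWarning, match="MS_error"):
            comp = tukey_kramer(_table(Y))
        assert comp.pairs.p_adjusted.iloc[0] == 0.0

    def test_orientation_controls_ordering(self):
        Y = np.array([[0.2, 0.5], [0.3, 0.65]])
        best_high = tukey_kramer(_table(Y, larger_is_better=True))
        best_low = tukey_kramer(_table(Y, larger_is_better=False))
        assert best_high.ordered_combos == ["c1", "c0"]
        assert best_low.ordered_combos == ["c0", "c1"]


class TestMcsMatrix:
    def test_all_identical_columns_nonsignificant(self, rng):
        base = rng.standard_normal(3)
        noise = rng.standard_normal((3, 4)) * 1e-1
        Y = base[:, None] + noise
        # large shared split effects, tiny combo differences
        comp = tukey_kramer(_table(Y))
        mat = mcs_matrix(comp)
        off = mat.to_numpy()[~np.eye(4, dtype=bool)]
        assert comp.anova.ms_error > 0
        assert set(np.diag(mat)) == {"self"}

    def test_dominant_combo_first_and_significant(self, rng):
        table = make_performance_table(s=3, c=5, sigma=0.05,
                                       elevated=(2, 10.0), seed=3)
        comp = tukey_kramer(table)
        mat = mcs_matrix(comp)
        assert comp.ordered_combos[0] == "combo3"
        row = mat.loc["combo3"].drop("combo3")
        assert (row == "p <= 0.01").all()

    def test_matrix_symmetric(self, rng):
        table = make_performance_table(s=4, c=6, sigma=0.2, seed=9)
        mat = mcs_matrix(tukey_kramer(table))
        assert (mat.to_numpy() == mat.to_numpy().T).all()
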