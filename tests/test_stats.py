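"""Visual-score aggregation, ICC(A,k) and Pearson correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cranioquant as cq
from cranioquant.phantom import ITEM_NAMES
from cranioquant.stats import (
    StatsError,
    aggregate_visual,
    icc_a_k,
    icc_label,
    pearson,
    r_label,
    rater_grid,
)


def _long_table(scores: np.ndarray) -> pd.DataFrame:
    """subjects x raters x 6 array -> long rater table."""
    n_s, n_r, n_i = scores.shape
    rows = [
        (s, r, ITEM_NAMES[i], int(scores[s, r, i]))
        for s in range(n_s) for r in range(n_r) for i in range(n_i)
    ]
    return pd.DataFrame(rows, columns=["subject", "rater", "item", "score"])


class TestAggregateVisual:
    def test_all_severe_gives_twelve(self):
        table = _long_table(np.full((4, 3, 6), 2))
        assert (aggregate_visual(table) == 12.0).all()

    def test_all_normal_gives_zero(self):
        table = _long_table(np.zeros((4, 3, 6), dtype=int))
        assert (aggregate_visual(table) == 0.0).all()

    def test_single_item_rater_mean(self):
        scores = np.zeros((2, 3, 6), dtype=int)
        scores[0, :, 0] = [0, 1, 2]  # one item scored 0/1/2 by the raters
        out = aggregate_visual(_long_table(scores))
        assert out.loc[0] == pytest.approx(1.0)
        assert out.loc[1] == pytest.approx(0.0)

    def test_missing_cell_named_in_error(self):
        table = _long_table(np.ones((3, 3, 6), dtype=int))
        table = table.drop(table[(table.subject == 1) & (table.rater == 2)
                                 & (table.item == ITEM_NAMES[0])].index)
        with pytest.raises(StatsError, match="missing"):
            aggregate_visual(table)


class TestICC:
    def test_identical_raters_give_one(self):
        grid = np.column_stack([[1, 5, 3, 9, 7]] * 3)
        res = icc_a_k(grid)
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.label == "excellent"

    def test_three_by_three_brute_force_anova(self):
        """Independent sums-of-squares decomposition written out longhand
        must match the packaged formula to 1e-9."""
        x = np.array([[2.0, 1.0, 2.0], [4.0, 5.0, 6.0], [9.0, 8.0, 6.0]])
        n, k = x.shape
        grand = x.sum() / x.size
        ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
        ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
        ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
        ms_rows = ss_rows / (n - 1)
        ms_cols = ss_cols / (k - 1)
        ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
        expected = (ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n)
        res = icc_a_k(x)
        assert res.icc == pytest.approx(expected, abs=1e-9)

    def test_against_pingouin_icc2k(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1)) * 2
        df = pd.DataFrame(x).reset_index().melt("index", var_name="rater", value_name="y")
        icc_tab = pg.intraclass_corr(
            data=df, targets="index", raters="rater", ratings="y"
        ).set_index("Type")
        assert icc_a_k(x).icc == pytest.approx(icc_tab.loc["ICC(A,k)", "ICC"], abs=1e-9)

    def test_zero_between_subject_variance_undefined(self):
        res = icc_a_k(np.array([[3.0, 3.0], [3.0, 3.0]]))
        assert res.icc is None
        assert "undefined" in res.reason

    @pytest.mark.parametrize("offset,scale", [(10.0, 1.0), (0.0, 3.5), (-4.0, 0.2)])
    def test_affine_invariance(self, offset, scale):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        a = icc_a_k(x).icc
        b = icc_a_k(x * scale + offset).icc
        assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize(
        "value,label",
        [(0.05, "poor"), (0.20, "fair"), (0.39, "fair"), (0.40, "moderate"),
         (0.60, "good"), (0.79, "good"), (0.80, "excellent"), (0.81, "excellent"),
         (1.0, "excellent")],
    )
    def test_landis_koch_bins(self, value, label):
        assert icc_label(value) == label

    def test_needs_two_by_two(self):
        with pytest.raises(StatsError):
            icc_a_k(np.array([[1.0, 2.0]]))


class TestPearson:
    def test_perfect_positive_linear(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.label == "very high"

    def test_perfect_negative_linear(self):
        x = np.arange(10.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_symmetry_and_positive_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r, abs=1e-12)
        assert pearson(x, y).r == pytest.approx(pearson(2 * x + 3, y).r, abs=1e-12)

    def test_p_value_matches_t_transform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        res = pearson(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        p = 2 * sps.t.sf(abs(t), res.n - 2)
        assert res.p == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize(
        "r,label",
        [(0.1, "negligible"), (0.29, "negligible"), (0.30, "low"), (0.49, "low"),
         (0.50, "moderate"), (0.59, "moderate"), (-0.59, "moderate"),
         (0.70, "high"), (-0.81, "high"), (0.90, "very high"), (1.0, "very high")],
    )
    def test_strength_bins(self, r, label):
        assert r_label(r) == label

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            pearson(np.ones(5), np.arange(5.0))

    def test_short_input_rejected(self):
        with pytest.raises(StatsError):
            pearson(np.array([1.0, 2.0]), np.array([2.0, 1.0]))


def test_label_bins_partition_unit_interval():
    """Every value in [0, 1] maps to exactly one label and the mapping is
    monotone step-wise (no gaps or overlaps at the printed edges)."""
    grid = np.round(np.linspace(0, 1, 101), 2)
    icc_seq = [icc_label(v) for v in grid]
    r_seq = [r_label(v) for v in grid]
    for seq, order in (
        (icc_seq, ["poor", "fair", "moderate", "good", "excellent"]),
        (r_seq, ["negligible", "low", "moderate", "high", "very high"]),
    ):
        assert [s for s in dict.fromkeys(seq)] == order  # each appears, in order


def test_rater_grid_totals(stats_table=None):
    table = cq.make_rater_table(6, 3, agreement=0.8, seed=11)
    grid = rater_grid(table)
    assert grid.shape == (6, 3)
    assert grid.to_numpy().max() <= 12 and grid.to_numpy().min() >= 0
    one_item = rater_grid(table, item="width")
    assert one_item.to_numpy().max() <= 2


def test_correlation_matrix_layout(cohort_features):
    import pandas as pd

    feats = pd.DataFrame(
        {"O": [f.O for f in cohort_features], "width": [f.width for f in cohort_features]}
    )
    target = pd.DataFrame({"visual": np.linspace(0, 12, len(cohort_features))})
    mat = cq.correlation_matrix(feats, target)
    assert set(mat.columns) == {"visual_r", "visual_p", "visual_n", "visual_label"}
    assert mat.loc["O", "visual_n"] == len(cohort_features)
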