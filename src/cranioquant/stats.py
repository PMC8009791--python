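"""Rater-score aggregation, interrater ICC and Pearson correlation.

The visual severity score is aggregated per subject as the rater mean of
each of the six items, summed over items (range 0-12).  Interrater
reliability uses the intraclass correlation in its two-way random-effects,
absolute-agreement, average-measures form, ICC(A,k), computed from the
two-way ANOVA decomposition.  Associations are measured with Pearson's
product-moment correlation and a two-sided t-test p-value.  Both
statistics carry the conventional verbal interpretation labels
(Landis-Koch categories for ICC, correlation-strength categories for |r|);
since the printed category edges abut (e.g. "0.61 to 0.80" then "0.81 to
1.00"), the bins are implemented lower-inclusive at .20/.40/.60/.80 (ICC)
and .30/.50/.70/.90 (|r|) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ICC_MODEL = "two-way random, absolute agreement, average measures (ICC(A,k))"

#: lower edges of the Landis-Koch reliability categories
ICC_BINS = ((0.80, "excellent"), (0.60, "good"), (0.40, "moderate"), (0.20, "fair"), (0.0, "poor"))
#: lower edges of the correlation-strength categories (applied to |r|)
R_BINS = ((0.90, "very high"), (0.70, "high"), (0.50, "moderate"), (0.30, "low"), (0.0, "negligible"))


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ICCResult:
    icc: float | None
    model: str
    label: str | None
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int
    reason: str | None = None  # set when the ICC is undefined


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    label: str


def rater_grid(table: pd.DataFrame, item: str | None = None) -> pd.DataFrame:
    """Pivot a long rater table to subjects x raters.

    ``item`` selects one of the six items; None sums the items per
    (subject, rater), i.e. each rater's total 0-12 score.  Missing cells
    are rejected with their (subject, rater, item) addresses.
    """
    t = table if item is None else table[table["item"] == item]
    if item is not None and t.empty:
        raise StatsError(f"no rows for item {item!r}")
    counts = t.pivot_table(index="subject", columns="rater", values="score", aggfunc="count")
    expected = t["item"].nunique()
    bad = counts.isna() | (counts != expected)
    if bad.to_numpy().any():
        cells = [(s, r) for s, r in zip(*np.where(bad.to_numpy()))]
        labels = [(counts.index[s], counts.columns[r]) for s, r in cells]
        raise StatsError(f"incomplete rater table at (subject, rater) cells: {labels}")
    return t.pivot_table(index="subject", columns="rater", values="score", aggfunc="sum")


def aggregate_visual(table: pd.DataFrame) -> pd.Series:
    """Overall visual score per subject: rater mean per item, summed.

    Each of the six items is averaged over the raters, and the six
    averages are summed, giving a score in [0, 12].
    """
    required = {"subject", "rater", "item", "score"}
    if not required.issubset(table.columns):
        raise StatsError(f"rater table needs columns {sorted(required)}")
    wide = table.pivot_table(
        index="subject", columns=["item", "rater"], values="score", aggfunc="first"
    )
    if wide.isna().to_numpy().any():
        missing = [
            (subj, item, rater)
            for subj, row in wide.iterrows()
            for (item, rater), v in row.items()
            if pd.isna(v)
        ]
        raise StatsError(f"missing rater scores at (subject, item, rater): {missing}")
    per_item_mean = wide.T.groupby(level="item").mean().T
    out = per_item_mean.sum(axis=1)
    out.name = "visual_score"
    return out


def icc_a_k(grid) -> ICCResult:
    """ICC(A,k) of a subjects x raters grid.

    Two-way ANOVA mean squares give
    ``(MS_rows - MS_err) / (MS_rows + (MS_cols - MS_err) / n)``.  With no
    between-subject variance the coefficient is undefined and reported as
    such rather than forced to a number.
    """
    x = np.asarray(grid, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise StatsError("ICC needs a 2-D grid with >= 2 subjects and >= 2 raters")
    if np.any(~np.isfinite(x)):
        raise StatsError("ICC grid contains missing or non-finite values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (ms_cols - ms_err) / n
    if ms_rows <= 1e-12 or abs(denom) <= 1e-12:
        return ICCResult(
            icc=None, model=ICC_MODEL, label=None,
            ms_rows=ms_rows, ms_cols=ms_cols, ms_error=ms_err,
            n_subjects=n, n_raters=k,
            reason="no between-subject variance; ICC undefined",
        )
    icc = (ms_rows - ms_err) / denom
    return ICCResult(
        icc=float(icc), model=ICC_MODEL, label=icc_label(icc),
        ms_rows=float(ms_rows), ms_cols=float(ms_cols), ms_error=float(ms_err),
        n_subjects=n, n_raters=k,
    )


def pearson(x, y) -> CorrelationResult:
    """Pearson r with two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise StatsError("correlation needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size), label=r_label(r))


def _bin_label(value: float, bins) -> str:
    for lo, name in bins:
        if value >= lo:
            return name
    return bins[-1][1]


def icc_label(icc: float, bins=ICC_BINS) -> str:
    """Landis-Koch reliability category (lower-inclusive bins)."""
    return _bin_label(max(icc, 0.0), bins)


def r_label(r: float, bins=R_BINS) -> str:
    """Correlation-strength category of |r| (lower-inclusive bins)."""
    return _bin_label(min(abs(r), 1.0), bins)


def correlation_matrix(features_df: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Pearson r / p / label for every (feature column, target column) pair.

    Mirrors the study layout of curve variables correlated against visual
    scores.  Rows are feature columns, with one (r, p, n, label) block per
    target column.
    """
    records = []
    for fcol in features_df.columns:
        rec: dict = {"feature": fcol}
        for tcol in targets.columns:
            res = pearson(features_df[fcol].to_numpy(), targets[tcol].to_numpy())
            rec[f"{tcol}_r"] = res.r
            rec[f"{tcol}_p"] = res.p
            rec[f"{tcol}_n"] = res.n
            rec[f"{tcol}_label"] = res.label
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("feature")
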