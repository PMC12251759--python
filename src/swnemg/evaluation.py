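"""Differential classification accuracy, window-sweep selection and the
nonparametric statistics used to compare normalization conditions.

The robustness metric is the differential classification accuracy

    y[n, i, j] = x[n, i, j] - x_baseline[n, j, j]

where ``x[n, i, j]`` is the frame-level accuracy of a model trained at
electrode position ``i`` and tested at position ``j`` under normalization
condition ``n``, and the baseline is the same-position accuracy at ``j``.
Negative values quantify the cost of the electrode shift; zero means the
shift is fully compensated.

Group comparisons use the Wilcoxon rank-sum test (exact enumeration for
small untied samples, tie-corrected normal approximation with continuity
correction otherwise) with Bonferroni correction, and the two-way
Scheirer-Ray-Hare test -- a rank-transform ANOVA whose effect statistics
``H = SS_effect / MS_total`` (tie-corrected) are chi-square distributed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "DIFF_TABLE_COLUMNS",
    "SweepGrid",
    "accuracy",
    "differential_accuracy",
    "make_diff_table",
    "select_best",
    "wilcoxon_rank_sum",
    "bonferroni",
    "scheirer_ray_hare",
    "aggregate_subject_means",
]

DIFF_TABLE_COLUMNS = [
    "normalization",
    "strategy",
    "train_position",
    "test_position",
    "subject",
    "accuracy",
    "baseline_accuracy",
    "diff_accuracy",
]


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Frame-level classification accuracy (successes over total)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be equal-length and nonempty")
    return float(np.mean(predictions == labels))


def differential_accuracy(x: float, x_baseline: float) -> float:
    """Cross-position accuracy minus the same-position baseline accuracy."""
    return x - x_baseline


def make_diff_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble and validate a differential-accuracy table.

    Each row carries (normalization, strategy, train i, test j, subject,
    x, x_baseline); the difference column is recomputed so that
    ``diff = x - x_baseline`` holds exactly on every row.
    """
    df = pd.DataFrame(rows)
    df["diff_accuracy"] = df["accuracy"] - df["baseline_accuracy"]
    bad = df[(df["accuracy"] < 0) | (df["accuracy"] > 1)]
    if len(bad):
        raise ValueError("accuracies must lie in [0, 1]")
    return df[DIFF_TABLE_COLUMNS]


@dataclass
class SweepGrid:
    """Accuracy per (norm window, feature window) cell.

    ``results`` columns: norm_ms (0 for the no-normalization condition),
    feature_ms, combo (train->test position pair), subject, accuracy.
    """

    norm_windows: tuple
    feature_windows: tuple
    results: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return max(1, len(self.norm_windows)) * len(self.feature_windows)


def select_best(sweep: SweepGrid) -> tuple[tuple[float, float], float]:
    """Cell with maximal mean accuracy across (combo, subject).

    Returns ``((norm_ms, feature_ms), mean_accuracy)``; ties break toward the
    smaller feature window, then the smaller norm window.  Raises when any
    grid cell has no observations.
    """
    norms = sweep.norm_windows if sweep.norm_windows else (0,)
    expected = {(n, f) for n in norms for f in sweep.feature_windows}
    present = set(map(tuple, sweep.results[["norm_ms", "feature_ms"]].drop_duplicates().values))
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"incomplete sweep grid; missing cells: {missing}")
    means = (
        sweep.results.groupby(["norm_ms", "feature_ms"])["accuracy"].mean().reset_index()
    )
    means = means.sort_values(
        ["accuracy", "feature_ms", "norm_ms"], ascending=[False, True, True]
    )
    top = means.iloc[0]
    return (float(top["norm_ms"]), float(top["feature_ms"])), float(top["accuracy"])


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(rank_sum_of_a, p_two_sided)`` using mid-ranks for ties.  The
    p-value is exact (full enumeration of rank assignments) for untied
    samples with ``n_a + n_b <= 12``, otherwise a normal approximation with
    tie-corrected variance and continuity correction.  The statistic and
    p-value are shift-invariant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size + b.size <= 12:
        method = "exact"
    else:
        method = "asymptotic"
    # The Mann-Whitney U statistic is a monotone shift of the rank sum, so its
    # exact/asymptotic two-sided p-value is the rank-sum test's p-value.
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                              use_continuity=True)
    return w, float(res.pvalue)


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment ``p' = min(1, m p)``."""
    p = np.asarray(p_values, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def scheirer_ray_hare(values, factor_a, factor_b) -> pd.DataFrame:
    """Two-way Scheirer-Ray-Hare rank test.

    Ranks all N observations (mid-ranks for ties), computes the two-way
    ANOVA sums of squares on the ranks, and forms, per effect (A, B, A x B),

        H = SS_effect / MS_total,    MS_total = SS_total / (N - 1),

    with ``H ~ chi-square`` under the null at the effect's ANOVA degrees of
    freedom.  Because MS_total is computed from the observed mid-ranks, the
    classical tie-correction divisor D = 1 - sum(t^3 - t)/(N^3 - N) is
    already implicit: SS_total/(N-1) equals D * N(N+1)/12 identically, so
    this H reduces exactly to the tie-corrected Kruskal-Wallis statistic
    when one factor has a single level.  The design must be complete (every A x B cell observed) with at
    least two levels per factor and two observations per cell.

    Returns a DataFrame indexed by effect with columns H, df, p.
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (values.shape == fa.shape == fb.shape) or values.ndim != 1:
        raise ValueError("values and factors must be equal-length 1-D arrays")
    a_levels = np.unique(fa)
    b_levels = np.unique(fb)
    if a_levels.size < 2 or b_levels.size < 1:
        raise ValueError("factor A needs >= 2 levels")
    n = values.size
    for al in a_levels:
        for bl in b_levels:
            cnt = np.sum((fa == al) & (fb == bl))
            if cnt < 2:
                raise ValueError(f"cell ({al!r}, {bl!r}) has {cnt} < 2 observations")

    r = sstats.rankdata(values)
    grand = r.mean()
    ss_total = float(((r - grand) ** 2).sum())
    if ss_total == 0.0:
        rows = [
            {"effect": "A", "H": 0.0, "df": int(a_levels.size - 1), "p": 1.0},
            {"effect": "B", "H": 0.0, "df": int(max(b_levels.size - 1, 0)), "p": 1.0},
            {
                "effect": "A:B",
                "H": 0.0,
                "df": int((a_levels.size - 1) * max(b_levels.size - 1, 0)),
                "p": 1.0,
            },
        ]
        return pd.DataFrame(rows).set_index("effect")

    def ss_marginal(factor, levels):
        ss = 0.0
        for lv in levels:
            mask = factor == lv
            ss += mask.sum() * (r[mask].mean() - grand) ** 2
        return float(ss)

    ss_a = ss_marginal(fa, a_levels)
    ss_b = ss_marginal(fb, b_levels)
    ss_cells = 0.0
    for al in a_levels:
        for bl in b_levels:
            mask = (fa == al) & (fb == bl)
            ss_cells += mask.sum() * (r[mask].mean() - grand) ** 2
    ss_ab = float(ss_cells - ss_a - ss_b)

    ms_total = ss_total / (n - 1)  # tie correction implicit (see docstring)

    rows = []
    for name, ss, df in (
        ("A", ss_a, a_levels.size - 1),
        ("B", ss_b, max(b_levels.size - 1, 0)),
        ("A:B", ss_ab, (a_levels.size - 1) * max(b_levels.size - 1, 0)),
    ):
        if df == 0:
            rows.append({"effect": name, "H": 0.0, "df": 0, "p": 1.0})
            continue
        h = ss / ms_total
        rows.append(
            {"effect": name, "H": float(h), "df": int(df), "p": float(sstats.chi2.sf(h, df))}
        )
    return pd.DataFrame(rows).set_index("effect")


def aggregate_subject_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean differential accuracy over position combinations, per
    (normalization, strategy, subject) -- the unit fed to the rank tests."""
    needed = {"normalization", "strategy", "subject", "diff_accuracy"}
    if not needed <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(needed)}")
    return (
        table.groupby(["normalization", "strategy", "subject"])["diff_accuracy"]
        .mean()
        .reset_index()
        .rename(columns={"diff_accuracy": "mean_diff_accuracy"})
    )
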