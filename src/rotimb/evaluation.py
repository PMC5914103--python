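"""Benchmark protocol: repeated stratified cross-validation, paired t-tests,
summary tables, and tie-averaged ranks.

The standard protocol is ten repetitions of 10-fold cross-validation (100
fitted models per method and dataset).  Per-cell results are compared to a
reference method with a two-sided paired t-test at the 0.05 level; summary
tables mark cells where the reference is significantly better (bullet) or
worse (open circle).  Methods are ranked per dataset — best score gets
rank 1.0, ties receive the average of the tied ranks — and ranks are then
averaged over datasets.

No correction is applied for the correlation between cross-validation
folds, so the t-tests are anticonservative; they are a descriptive
convention of this benchmark style, not a calibrated inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .io_data import LabeledDataset
from .metrics import MetricConfig, compute_all

METRIC_NAMES = ("accuracy", "precision", "recall", "f_measure", "g_mean", "auc")

A_BETTER = "a_better_significant"
B_BETTER = "b_better_significant"
NOT_SIG = "not_significant"


@dataclass(frozen=True)
class CVPlan:
    """folds x repetitions cross-validation layout (default 10 x 10)."""

    folds: int = 10
    repetitions: int = 10
    seed: int = 0
    stratified: bool = True


@dataclass(frozen=True)
class RankTable:
    """Per-dataset tie-averaged ranks and their per-method averages."""

    ranks: pd.DataFrame  # index: dataset, columns: methods
    average: pd.Series  # per-method mean rank over datasets


def make_folds(
    ds: LabeledDataset, plan: CVPlan
) -> list[tuple[np.ndarray, np.ndarray]]:
    """All (train, test) index pairs of the repeated CV plan.

    Each repetition partitions every example into ``plan.folds`` disjoint
    test folds; stratified folding keeps per-fold class proportions within
    one example of the dataset's.  When the minority class has fewer
    examples than folds, stratification is impossible and plain K-fold is
    used instead (with a warning).
    """
    N = ds.n_examples
    if N < plan.folds:
        raise ValueError(f"need at least {plan.folds} examples, have {N}")
    stratified = plan.stratified
    if stratified and min(ds.n_abnormal, ds.n_normal) < plan.folds:
        warnings.warn(
            "minority class smaller than the fold count; falling back to "
            "unstratified folds",
            stacklevel=2,
        )
        stratified = False
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in range(plan.repetitions):
        state = plan.seed * 1000 + rep
        if stratified:
            splitter = StratifiedKFold(plan.folds, shuffle=True, random_state=state)
            split_iter = splitter.split(ds.features, ds.labels)
        else:
            splitter = KFold(plan.folds, shuffle=True, random_state=state)
            split_iter = splitter.split(ds.features)
        pairs.extend((np.asarray(tr), np.asarray(te)) for tr, te in split_iter)
    return pairs


def _subset(ds: LabeledDataset, idx: np.ndarray) -> LabeledDataset:
    return LabeledDataset(
        features=ds.features[idx],
        labels=ds.labels[idx],
        feature_names=ds.feature_names,
        nominal_domains=dict(ds.nominal_domains),
    )


def run_benchmark(
    ds: LabeledDataset,
    methods: Mapping[str, Callable],
    plan: CVPlan,
    metric_cfg: MetricConfig = MetricConfig(),
    dataset_name: str = "dataset",
) -> pd.DataFrame:
    """Train every method on every CV split and score the paired test fold.

    ``methods`` maps a name to a ``fit(train_dataset, rng) -> model``
    callable whose model exposes ``predict``.  Returns the long-format
    result grid with columns (dataset, method, repetition, fold, metric,
    value); each (method, metric) cell holds folds x repetitions values.
    Every fit receives its own seed stream derived from the plan seed, so
    a rerun with the same plan reproduces the grid bit-for-bit.
    """
    if not methods:
        raise ValueError("methods must be nonempty")
    pairs = make_folds(ds, plan)
    rows = []
    for m_index, (name, fit) in enumerate(methods.items()):
        for pair_index, (train_idx, test_idx) in enumerate(pairs):
            rep, fold = divmod(pair_index, plan.folds)
            train = _subset(ds, train_idx)
            rng = np.random.default_rng([plan.seed, m_index, rep, fold])
            try:
                model = fit(train, rng)
                y_pred = model.predict(ds.features[test_idx])
            except Exception as exc:
                raise RuntimeError(
                    f"method {name!r} failed on repetition {rep}, fold {fold}: {exc}"
                ) from exc
            scores = compute_all(ds.labels[test_idx], y_pred, metric_cfg)
            for metric, value in scores.items():
                rows.append(
                    {
                        "dataset": dataset_name,
                        "method": name,
                        "repetition": rep,
                        "fold": fold,
                        "metric": metric,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def paired_t_test(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> str:
    """Two-sided paired Student t-test on matched per-fold scores.

    Returns which side is significantly better at level ``alpha`` (by mean
    difference), or ``not_significant``.  Degenerate zero-variance
    differences: all-zero means not significant; a nonzero constant
    difference is treated as significant by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples of size >= 2")
    diff = a - b
    mean = diff.mean()
    if np.allclose(diff, diff[0]):
        if mean == 0:
            return NOT_SIG
        return A_BETTER if mean > 0 else B_BETTER
    _, p = stats.ttest_rel(a, b)
    if p < alpha:
        return A_BETTER if mean > 0 else B_BETTER
    return NOT_SIG


def _cell_values(grid: pd.DataFrame, dataset: str, method: str, metric: str) -> np.ndarray:
    sel = grid[
        (grid["dataset"] == dataset)
        & (grid["method"] == method)
        & (grid["metric"] == metric)
    ].sort_values(["repetition", "fold"])
    return sel["value"].to_numpy()


def significance_marks(
    grid: pd.DataFrame, reference: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per (dataset, method != reference, metric) significance mark.

    ``better`` means the reference significantly outperforms the method
    (rendered as a bullet), ``worse`` the opposite (open circle), ``none``
    no significant difference.
    """
    methods = grid["method"].unique()
    if reference not in methods:
        raise ValueError(f"reference {reference!r} not in grid")
    rows = []
    for dataset in grid["dataset"].unique():
        for metric in grid["metric"].unique():
            ref_values = _cell_values(grid, dataset, reference, metric)
            for method in methods:
                if method == reference:
                    continue
                other = _cell_values(grid, dataset, method, metric)
                if np.isnan(ref_values).any() or np.isnan(other).any():
                    mark = "none"
                else:
                    outcome = paired_t_test(ref_values, other, alpha)
                    mark = {A_BETTER: "better", B_BETTER: "worse", NOT_SIG: "none"}[outcome]
                rows.append(
                    {"dataset": dataset, "method": method, "metric": metric, "mark": mark}
                )
    return pd.DataFrame(rows)


def average_ranks(values: pd.DataFrame, higher_is_better: bool = True) -> RankTable:
    """Tie-averaged competition ranks per dataset, averaged per method.

    ``values`` holds one score per (dataset row, method column).  The best
    method in a row gets rank 1.0, the next 2.0, and so on; tied methods
    share the average of the ranks they span, so each row's ranks always
    sum to m(m+1)/2.
    """
    if values.isna().any().any():
        raise ValueError("missing values in the score table")
    if values.shape[1] < 2 or values.shape[0] < 1:
        raise ValueError("need at least 2 methods and 1 dataset")
    signed = -values.to_numpy(dtype=float) if higher_is_better else values.to_numpy(dtype=float)
    ranks = np.vstack([stats.rankdata(row, method="average") for row in signed])
    rank_df = pd.DataFrame(ranks, index=values.index, columns=values.columns)
    return RankTable(ranks=rank_df, average=rank_df.mean(axis=0))


def grid_to_table(grid: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pivot the result grid to a dataset x method table of mean scores."""
    sub = grid[grid["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} not present in grid")
    return sub.pivot_table(index="dataset", columns="method", values="value", aggfunc="mean")


def summarize(grid: pd.DataFrame) -> pd.DataFrame:
    """Mean and spread per (dataset, method, metric), plus per-method averages.

    The ``sd`` column is the sample standard deviation of the per-fold
    values (this is what the +/- column of benchmark tables of this style
    reports — it is not the standard error of the mean).  An extra
    ``dataset='average'`` block holds the unweighted mean over datasets.
    """
    if grid["value"].isna().any():
        raise ValueError("incomplete grid: NaN values present")
    per_cell = (
        grid.groupby(["dataset", "method", "metric"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    averages = (
        per_cell.groupby(["method", "metric"])["mean"]
        .mean()
        .reset_index()
        .assign(dataset="average", sd=np.nan, n=np.nan)
    )
    return pd.concat([per_cell, averages[per_cell.columns]], ignore_index=True)


_MARK_SYMBOL = {"better": "●", "worse": "○", "none": ""}


def render_summary(
    grid: pd.DataFrame, metric: str, reference: str, alpha: float = 0.05
) -> str:
    """Text table of mean +/- sd per dataset and method, with significance marks.

    A bullet next to a cell means the reference method significantly
    outperforms that method on that dataset; an open circle the reverse.
    """
    summary = summarize(grid)
    marks = significance_marks(grid[grid["metric"] == metric], reference, alpha)
    mark_map = {
        (r["dataset"], r["method"]): _MARK_SYMBOL[r["mark"]] for _, r in marks.iterrows()
    }
    sub = summary[summary["metric"] == metric]
    methods = [reference] + sorted(set(sub["method"]) - {reference})
    datasets = [d for d in sub["dataset"].unique() if d != "average"] + ["average"]
    width = 20
    lines = ["Dataset".ljust(12) + "".join(m.ljust(width) for m in methods)]
    for dataset in datasets:
        cells = []
        for method in methods:
            row = sub[(sub["dataset"] == dataset) & (sub["method"] == method)]
            if row.empty:
                cells.append("-".ljust(width))
                continue
            mean = float(row["mean"].iloc[0])
            if dataset == "average":
                text = f"{mean:.4f}"
            else:
                text = f"{mean:.4f} ± {float(row['sd'].iloc[0]):.4f}"
            text += mark_map.get((dataset, method), "")
            cells.append(text.ljust(width))
        lines.append(dataset.ljust(12) + "".join(cells))
    return "\n".join(lines)
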