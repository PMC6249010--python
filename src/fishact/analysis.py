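"""Trace-level analyses: binning, heat maps, cessation detection, outlier
exclusion, group statistics and the validation curve fits.

The statistical unit throughout is the per-animal mean activity — group
comparisons run one-way ANOVA followed by Tukey's HSD on one mean per
animal, which avoids pseudo-replication across time bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pipeline import ActivityTrace

__all__ = [
    "BinnedTrace",
    "ConditionGroup",
    "GroupComparison",
    "LinearFit",
    "SigmoidFit",
    "bin_trace",
    "heatmap_matrix",
    "plot_heatmap",
    "detect_cessation",
    "exclude_highest_variance",
    "compare_groups",
    "fit_linear",
    "fit_sigmoid",
    "sigmoid",
    "significance_stars",
]


@dataclass(frozen=True)
class BinnedTrace:
    """Mean activity per half-open time bin [k*w, (k+1)*w), anchored at t=0.

    Empty bins are NaN (missing), never zero: a bin with no samples says
    nothing about the animal's activity in it.
    """

    bin_width: float
    bin_start_times: np.ndarray
    bin_means: np.ndarray
    animal_id: str = ""
    condition: str = ""


@dataclass
class ConditionGroup:
    """All traces recorded under one chemical/concentration condition."""

    condition: str
    traces: list[ActivityTrace]

    @property
    def mean_activity_per_animal(self) -> np.ndarray:
        return np.array([t.activities.mean() for t in self.traces])


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA plus Tukey HSD over all condition pairs."""

    f_statistic: float
    anova_p: float
    tukey_pairs: list[tuple[str, str, float]]
    conditions: list[str]
    group_means: dict[str, float]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "condition_a": a,
                "condition_b": b,
                "mean_difference": self.group_means[b] - self.group_means[a],
                "adjusted_p": p,
                "stars": significance_stars(p),
            }
            for a, b, p in self.tukey_pairs
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class SigmoidFit:
    """Three-parameter logistic fit y = a / (1 + exp(-(x - x0)/b))."""

    a: float
    x0: float
    b: float
    r_squared: float
    converged: bool = True
    degenerate: bool = False

    def predict(self, x) -> np.ndarray:
        return sigmoid(np.asarray(x, dtype=float), self.a, self.x0, self.b)


def significance_stars(p: float) -> str:
    """Map an adjusted p-value to the conventional star annotation."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def bin_trace(trace: ActivityTrace, bin_width: float) -> BinnedTrace:
    """Average improved activity in half-open bins of ``bin_width`` seconds."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t = trace.times
    a = trace.activities
    idx = np.floor(t / bin_width).astype(int)
    n_bins = idx.max() + 1 if len(idx) else 0
    sums = np.bincount(idx, weights=a, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedTrace(
        bin_width=float(bin_width),
        bin_start_times=np.arange(n_bins) * float(bin_width),
        bin_means=means,
        animal_id=trace.animal_id,
        condition=trace.condition,
    )


def heatmap_matrix(groups: list[ConditionGroup], bin_width: float,
                   normalize: bool = False) -> pd.DataFrame:
    """One row per animal (grouped by condition), one column per time bin.

    Rows are indexed by (condition, animal_id); columns are bin start times
    in seconds.  With ``normalize`` each row is divided by its own maximum,
    showing each animal's activity pattern rather than its magnitude.
    """
    if not groups:
        raise ValueError("heatmap needs at least one condition group")
    rows, index = [], []
    for g in groups:
        for tr in g.traces:
            binned = bin_trace(tr, bin_width)
            rows.append(binned)
            index.append((g.condition, tr.animal_id))
    n_bins = max(len(b.bin_means) for b in rows)
    mat = np.full((len(rows), n_bins), np.nan)
    for i, b in enumerate(rows):
        mat[i, : len(b.bin_means)] = b.bin_means
    if normalize:
        with np.errstate(invalid="ignore", divide="ignore"):
            peak = np.nanmax(mat, axis=1, keepdims=True)
            mat = np.where(peak > 0, mat / peak, mat)
    return pd.DataFrame(
        mat,
        index=pd.MultiIndex.from_tuples(index, names=["condition", "animal_id"]),
        columns=np.arange(n_bins) * float(bin_width),
    )


def plot_heatmap(matrix: pd.DataFrame, path, cmap: str = "viridis") -> None:
    """Render a heat-map DataFrame (rows = animals, cols = bins) to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.12 * matrix.shape[1]), max(2.0, 0.3 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", interpolation="nearest",
                   cmap=cmap)
    ax.set_xlabel("time bin")
    ax.set_yticks(range(len(matrix.index)))
    ax.set_yticklabels([f"{c} / {a}" for c, a in matrix.index], fontsize=6)
    fig.colorbar(im, ax=ax, label="activity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def detect_cessation(trace: ActivityTrace, epsilon: float = 0.0,
                     hold: float = 600.0) -> float | None:
    """Earliest time t* with activity <= epsilon from t* to the end.

    Activity cessation is the assay's death proxy: an animal whose activity
    drops to the floor and stays there for at least ``hold`` seconds is
    scored dead at the onset of the quiet period.  Returns None if activity
    never ceases (or the terminal quiet period is shorter than ``hold``).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if hold <= 0:
        raise ValueError("hold must be positive")
    t = trace.times
    a = trace.activities
    if len(t) == 0:
        return None
    above = np.nonzero(a > epsilon)[0]
    if len(above) == 0:
        t_star = float(t[0])
    elif above[-1] == len(a) - 1:
        return None
    else:
        t_star = float(t[above[-1] + 1])
    if float(t[-1]) - t_star < hold:
        return None
    return t_star


def adaptive_epsilon(trace: ActivityTrace, baseline: float = 600.0,
                     quantile: float = 0.05) -> float:
    """Noise floor estimate: the 5th percentile of the first 10 minutes."""
    t = trace.times
    a = trace.activities
    head = a[t <= t[0] + baseline] if len(t) else a
    if len(head) == 0:
        return 0.0
    return float(np.quantile(head, quantile))


def exclude_highest_variance(group: ConditionGroup,
                             use_binned: float | None = None) -> ConditionGroup:
    """Drop the single animal with the largest variation in activity.

    Variation is the sample variance of the raw improved-activity series;
    pass ``use_binned=<bin width>`` to rank by variance of binned means
    instead.  Ties are broken by dropping the first trace in input order.
    """
    if len(group.traces) < 2:
        raise ValueError("need at least 2 traces to exclude one")
    variances = []
    for tr in group.traces:
        if use_binned is not None:
            vals = bin_trace(tr, use_binned).bin_means
            vals = vals[~np.isnan(vals)]
        else:
            vals = tr.activities
        variances.append(float(np.var(vals, ddof=1)) if len(vals) > 1 else 0.0)
    drop = int(np.argmax(variances))  # argmax takes the first maximum
    keep = [tr for i, tr in enumerate(group.traces) if i != drop]
    return ConditionGroup(condition=group.condition, traces=keep)


def compare_groups(groups: list[ConditionGroup]) -> GroupComparison:
    """One-way ANOVA + Tukey HSD on per-animal mean activities.

    Unbalanced group sizes are handled by the Tukey–Kramer variant (the
    statsmodels implementation).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    values, labels = [], []
    for g in groups:
        m = g.mean_activity_per_animal
        if len(m) < 2:
            raise ValueError(f"group {g.condition!r} has fewer than 2 animals")
        values.append(m)
        labels.extend([g.condition] * len(m))
    flat = np.concatenate(values)
    if np.allclose(np.var(flat), 0):
        # all observations identical: no variance to partition
        f_stat, p = 0.0, 1.0
        pairs = [
            (groups[i].condition, groups[j].condition, 1.0)
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        ]
    else:
        f_stat, p = stats.f_oneway(*values)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(flat, np.array(labels))
        # _results_table rows are (group1, group2, meandiff, ...)
        pairs = [
            (str(row[0]), str(row[1]), float(padj))
            for row, padj in zip(res._results_table.data[1:], res.pvalues)
        ]
    return GroupComparison(
        f_statistic=float(f_stat),
        anova_p=float(p),
        tukey_pairs=pairs,
        conditions=[g.condition for g in groups],
        group_means={g.condition: float(g.mean_activity_per_animal.mean())
                     for g in groups},
    )


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        # constant y: define R^2 = 0 (the fit explains no variance because
        # there is none to explain)
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares line fit with the SS-convention R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal; slope is undefined")
    slope, intercept = np.polyfit(x, y, 1)
    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0])
    r2 = _r_squared(y, slope * x + intercept)
    return LinearFit(slope=float(slope), intercept=float(intercept), r_squared=r2)


def sigmoid(x, a, x0, b):
    """Three-parameter logistic a / (1 + exp(-(x - x0)/b))."""
    return a / (1.0 + np.exp(-(np.asarray(x, dtype=float) - x0) / b))


def fit_sigmoid(x, y, starts: tuple[float, float, float] | None = None) -> SigmoidFit:
    """Least-squares fit of the three-parameter logistic.

    Default starting values: a = max(y), x0 = median(x), b = range(x)/4.
    Non-convergence is reported in the result, never raised silently past.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    if np.ptp(y) == 0:
        return SigmoidFit(a=float(y[0]), x0=float(np.median(x)), b=1.0,
                          r_squared=0.0, converged=False, degenerate=True)
    if starts is None:
        starts = (float(y.max()), float(np.median(x)), float(np.ptp(x)) / 4.0 or 1.0)
    try:
        popt, _ = optimize.curve_fit(sigmoid, x, y, p0=starts, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = np.array(starts), False
    r2 = _r_squared(y, sigmoid(x, *popt))
    return SigmoidFit(a=float(popt[0]), x0=float(popt[1]), b=float(popt[2]),
                      r_squared=r2, converged=converged)
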