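"""Time-dimensionality reduction of per-object features.

A live-imaging experiment yields, for every feature, a cloud of per-object
values at each hour.  Two complementary reductions are provided:

* **Population heatmaps** — per aggregation group (well or condition), the
  feature's values at each hour are histogrammed over bins spanning the
  group's global min/max ("dynamic bin size"), and each hour's histogram is
  normalized, giving an hours x bins matrix that visualizes how the
  population distribution drifts over time.

* **Trend reduction** — each hour is collapsed to a robust central value
  (by default the interquartile mean after excluding values more than
  ``sd_k`` population standard deviations from the hour's mean), the hourly
  series is fit by ordinary least squares against the acquisition index,
  and the fitted gradient (feature units per hour) becomes the feature's
  single time-reduced data point.

Gradients of all features, in registry order, form a *gradient signature
vector* for each (cell line, condition); Pearson correlation between
signature vectors quantifies how similar two cultures' dynamic phenotypes
are at a given condition level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientDataError, ParameterError
from .features import FeatureRegistry, default_registry
from .plate_model import feature_columns_of

#: Minimum number of hourly points required for a trend fit.
MIN_FIT_POINTS = 3


@dataclass(frozen=True)
class HistogramSpec:
    """Equal-width bins spanning a feature's global range within a group."""

    edges: np.ndarray
    degenerate: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def bin_size(self) -> float:
        return float(self.edges[1] - self.edges[0]) if not self.degenerate else 0.0


def compute_bin_spec(values: Sequence[float], n_bins: int = 50) -> HistogramSpec:
    """Dynamic bins: equal widths over [min, max] of all finite group values.

    The last bin is right-closed so the maximum falls inside bin ``n_bins``.
    If all values coincide the spec degenerates to a single bin containing
    that value.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise InputError("cannot build a histogram spec without finite values")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return HistogramSpec(edges=np.array([lo - 0.5, lo + 0.5]), degenerate=True)
    return HistogramSpec(edges=np.linspace(lo, hi, n_bins + 1))


@dataclass(frozen=True)
class PopulationHeatmap:
    """Hours x bins matrix of per-hour normalized feature histograms."""

    matrix: np.ndarray          # shape (n_hours, n_bins)
    hours: np.ndarray           # the hour index of each row
    populated: np.ndarray       # bool per row; all-zero rows are flagged False
    spec: HistogramSpec
    group_id: str
    feature_name: str

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin_{i + 1}" for i in range(self.matrix.shape[1])]
        out = pd.DataFrame(self.matrix, columns=cols)
        out.insert(0, "hour", self.hours)
        out.insert(1, "populated", self.populated)
        return out


def population_heatmap(
    objects: pd.DataFrame,
    feature_name: str,
    group_id: str = "",
    spec: HistogramSpec | None = None,
    n_bins: int = 50,
    normalization: Literal["row", "max"] = "row",
) -> PopulationHeatmap:
    """Histogram one feature over objects at each hour, normalized per row.

    ``objects`` is the (already group-filtered) object table.  Row
    normalization divides each hour by its object count so rows are
    probability distributions; "max" normalization divides the whole matrix
    by its maximum instead.
    """
    if feature_name not in objects.columns:
        raise KeyError(f"unknown feature column {feature_name!r}")
    values = objects[feature_name].to_numpy(float)
    spec = spec or compute_bin_spec(values, n_bins)
    hours = np.arange(int(objects["hour"].max()) + 1) if len(objects) else np.arange(0)
    matrix = np.zeros((len(hours), spec.n_bins))
    populated = np.zeros(len(hours), bool)
    for i, h in enumerate(hours):
        v = values[objects["hour"].to_numpy() == h]
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        counts, _ = np.histogram(v, bins=spec.edges)
        # np.histogram's last bin is right-closed, as required
        populated[i] = True
        if normalization == "row":
            matrix[i] = counts / v.size
        else:
            matrix[i] = counts
    if normalization == "max" and matrix.max() > 0:
        matrix = matrix / matrix.max()
    return PopulationHeatmap(matrix, hours, populated, spec, group_id, feature_name)


# ---------------------------------------------------------------------------
# Hourly statistic and trend fitting

Statistic = Literal["iq_mean", "iqr_width", "midhinge"]


def hourly_statistic(
    values: Sequence[float], sd_k: float = 3.0, statistic: Statistic = "iq_mean"
) -> float:
    """Robust central value of one hour's feature values.

    A single non-iterative pass removes values more than ``sd_k`` population
    standard deviations from the raw mean; the default statistic is then the
    interquartile mean of the remainder (mean of values between Q1 and Q3
    inclusive, quartiles by linear interpolation).  "iqr_width" (Q3 - Q1)
    and "midhinge" ((Q1 + Q3)/2) are provided as alternatives.
    """
    if sd_k <= 0:
        raise ParameterError("sd_k must be > 0")
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise InsufficientDataError("no finite values in hour")
    keep = np.abs(v - v.mean()) <= sd_k * v.std()
    v = v[keep]
    if v.size == 0:  # unreachable with a single pass and sd_k > 0
        raise InsufficientDataError("outlier exclusion removed every value")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    if statistic == "iqr_width":
        return float(q3 - q1)
    if statistic == "midhinge":
        return float((q1 + q3) / 2.0)
    core = v[(v >= q1) & (v <= q3)]
    return float(core.mean())


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of an hourly statistic against the acquisition index."""

    gradient: float
    intercept: float
    n_hours_used: int
    residual_se: float


def fit_trend(hours: Sequence[int], stats: Sequence[float],
              min_fit_points: int = MIN_FIT_POINTS) -> TrendFit:
    """Ordinary least squares of the hourly statistic on the hour index."""
    hours = np.asarray(hours, float)
    stats = np.asarray(stats, float)
    ok = np.isfinite(hours) & np.isfinite(stats)
    hours, stats = hours[ok], stats[ok]
    n = len(hours)
    if n < min_fit_points:
        raise InsufficientDataError(
            f"trend fit needs >= {min_fit_points} hours, got {n}"
        )
    if len(np.unique(hours)) != n or not np.all(np.diff(hours) > 0):
        order = np.argsort(hours)
        hours, stats = hours[order], stats[order]
        if len(np.unique(hours)) != n:
            raise InputError("hours must be unique")
    hbar, sbar = hours.mean(), stats.mean()
    sxx = float(((hours - hbar) ** 2).sum())
    gradient = float(((hours - hbar) * (stats - sbar)).sum() / sxx)
    intercept = float(sbar - gradient * hbar)
    resid = stats - (intercept + gradient * hours)
    dof = max(n - 2, 1)
    residual_se = float(np.sqrt((resid ** 2).sum() / dof))
    return TrendFit(gradient, intercept, n, residual_se)


def gradient_standard_error(fit: TrendFit, hours: Sequence[int]) -> float:
    """Standard error of the fitted gradient given the hour design points."""
    hours = np.asarray(hours, float)
    sxx = float(((hours - hours.mean()) ** 2).sum())
    return fit.residual_se / np.sqrt(sxx)


# ---------------------------------------------------------------------------
# Summary tables, signatures, correlation

GroupLevel = Literal["well", "condition"]


def _group_columns(level: GroupLevel) -> list[str]:
    if level == "well":
        return ["plate", "well"]
    if level == "condition":
        return ["cell_line", "condition"]
    raise ParameterError(f"unknown group level {level!r}")


def build_summary(
    objects: pd.DataFrame,
    registry: FeatureRegistry | None = None,
    group_level: GroupLevel = "condition",
    sd_k: float = 3.0,
    statistic: Statistic = "iq_mean",
    min_fit_points: int = MIN_FIT_POINTS,
) -> pd.DataFrame:
    """Reduce an annotated object table to one trend row per (group, feature).

    Columns: group_id, cell_line, condition, feature_name, gradient,
    intercept, n_hours_used, residual_se.  Groups with fewer than
    ``min_fit_points`` populated hours keep their row with NaN gradient.
    """
    registry = registry or default_registry()
    feature_cols = [c for c in registry.column_names if c in objects.columns]
    missing = set(registry.column_names) - set(feature_cols)
    if missing and len(objects):
        raise InputError(f"object table lacks registry columns: {sorted(missing)[:5]} ...")
    group_cols = _group_columns(group_level)
    rows = []
    if len(objects) == 0:
        return pd.DataFrame(columns=["group_id", "cell_line", "condition",
                                     "feature_name", "gradient", "intercept",
                                     "n_hours_used", "residual_se"])
    for key, grp in objects.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        group_id = "/".join(str(k) for k in key)
        cell_line = grp["cell_line"].iloc[0] if "cell_line" in grp else ""
        condition = grp["condition"].iloc[0] if "condition" in grp else ""
        hour_arr = grp["hour"].to_numpy()
        for col in feature_cols:
            vals = grp[col].to_numpy(float)
            hours, stats = [], []
            for h in np.unique(hour_arr):
                v = vals[hour_arr == h]
                v = v[np.isfinite(v)]
                if v.size == 0:
                    continue
                hours.append(int(h))
                stats.append(hourly_statistic(v, sd_k=sd_k, statistic=statistic))
            try:
                fit = fit_trend(hours, stats, min_fit_points=min_fit_points)
                grad, icpt, n_used, rse = (fit.gradient, fit.intercept,
                                           fit.n_hours_used, fit.residual_se)
            except InsufficientDataError:
                grad = icpt = rse = np.nan
                n_used = len(hours)
            rows.append({
                "group_id": group_id, "cell_line": cell_line,
                "condition": condition, "feature_name": col,
                "gradient": grad, "intercept": icpt,
                "n_hours_used": n_used, "residual_se": rse,
            })
    return pd.DataFrame(rows)


def signature_vectors(
    summary: pd.DataFrame, registry: FeatureRegistry | None = None
) -> pd.DataFrame:
    """Assemble per-(cell_line, condition) gradient signature vectors.

    Returns a DataFrame with one row per group (index = group_id) and one
    column per registry feature, in registry order.  Gradients missing from
    the summary stay NaN.
    """
    registry = registry or default_registry()
    if len(summary) == 0:
        return pd.DataFrame(columns=list(registry.column_names))
    index = ["cell_line", "condition"] if {
        "cell_line", "condition"}.issubset(summary.columns) else "group_id"
    pivot = summary.pivot_table(
        index=index, columns="feature_name", values="gradient",
        aggfunc="first", dropna=False,
    )
    return pivot.reindex(columns=list(registry.column_names)).sort_index()


def condition_correlations(
    vectors: pd.DataFrame, mode: Literal["raw", "zscore"] = "raw"
) -> dict[str, pd.DataFrame]:
    """One correlation matrix of the cell lines per condition level.

    ``vectors`` must be indexed by (cell_line, condition); conditions with
    fewer than two cell lines are skipped.
    """
    if not isinstance(vectors.index, pd.MultiIndex):
        raise InputError("vectors must be indexed by (cell_line, condition)")
    out = {}
    for cond, sub in vectors.groupby(level="condition"):
        sub = sub.droplevel("condition")
        if len(sub) >= 2:
            out[str(cond)] = correlation_matrix(sub, mode=mode)
    return out


def correlation_matrix(
    vectors: pd.DataFrame, mode: Literal["raw", "zscore"] = "raw"
) -> pd.DataFrame:
    """Pearson correlation between gradient signature vectors.

    Rows of ``vectors`` are signatures; missing entries are dropped pairwise.
    "zscore" standardizes each feature across vectors first, which puts
    features with heterogeneous units on a common scale.  The result is
    symmetric with a unit diagonal; pairs with fewer than two overlapping
    features are NaN.
    """
    if len(vectors) < 2:
        raise InputError("need at least two signature vectors")
    data = vectors.copy()
    if mode == "zscore":
        mu = data.mean(axis=0)
        sd = data.std(axis=0, ddof=0)
        sd = sd.replace(0.0, np.nan)
        data = (data - mu) / sd
    corr = data.T.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr
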