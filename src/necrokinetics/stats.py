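"""Group-discrimination and association statistics for biomarker cohorts.

Implements the small statistical toolkit used to compare CSF biomarker
concentrations between diagnostic groups: the Wilcoxon rank-sum
(Mann-Whitney U) test with Bonferroni correction, empirical ROC curves
with trapezoidal AUC, Pearson correlation, and the box-plot five-number
summary (whiskers at 1.5x the interquartile range).

The test statistics are computed here rather than delegated: the exact
rank-sum null distribution is built by the shift-algorithm dynamic
programme (equivalent to exhaustively enumerating all group assignments)
for untied samples with n*m <= 400, and the normal approximation uses the
tie-corrected variance with a continuity correction.  Only distribution
functions (normal, Student t) come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _spstats

__all__ = [
    "BiomarkerDataset",
    "TestResult",
    "RocCurve",
    "BoxSummary",
    "rank_sum_test",
    "bonferroni_adjust",
    "roc_points",
    "auc",
    "pearson_r",
    "box_summary",
    "compare_groups",
]

EXACT_LIMIT = 400  # exact rank-sum enumeration when n*m is at most this


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiomarkerDataset:
    """Subject-level biomarker concentrations with group labels.

    ``records`` has columns ``subject_id``, ``group`` and ``value_pg_ml``
    (strictly positive concentrations).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = {"subject_id", "group", "value_pg_ml"} - set(df.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("records is empty")
        if np.any(df["value_pg_ml"].to_numpy(dtype=float) <= 0):
            raise ValueError("concentrations must be > 0")

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.records["group"]))

    def group_values(self, name: str) -> np.ndarray:
        vals = self.records.loc[
            self.records["group"] == name, "value_pg_ml"
        ].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"unknown or empty group: {name!r}")
        return vals


@dataclass(frozen=True)
class TestResult:
    """Rank-sum test outcome (U for the first sample, two-sided p)."""

    statistic: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int
    method: str  # "exact" or "normal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= self.p_adjusted <= 1.0:
            raise ValueError("require 0 <= p_raw <= p_adjusted <= 1")


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC operating points from (0,0) to (1,1), with AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        fpr, tpr = np.asarray(self.fpr, float), np.asarray(self.tpr, float)
        ok = (
            fpr.shape == tpr.shape
            and np.all((fpr >= 0) & (fpr <= 1))
            and np.all((tpr >= 0) & (tpr <= 1))
            and np.all(np.diff(fpr) >= 0)
            and np.all(np.diff(tpr) >= 0)
            and 0.0 <= self.auc <= 1.0
        )
        if not ok:
            raise ValueError("invalid ROC curve")


@dataclass(frozen=True)
class BoxSummary:
    """Median, quartiles, and 1.5x-IQR whiskers (in the data's units)."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float

    def __post_init__(self) -> None:
        if not (
            self.whisker_low <= self.q1 <= self.median
            <= self.q3 <= self.whisker_high
        ):
            raise ValueError("box summary ordering violated")


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # average of ranks i+1..j+1
        i = j + 1
    return ranks


def _exact_u_counts(n: int, m: int) -> np.ndarray:
    """Number of assignments achieving each U value, untied samples.

    counts[u] over u = 0..n*m, built by the classic recurrence over
    placements; the total is C(n+m, n), i.e. an exhaustive enumeration of
    all group labellings.
    """
    # c[i, j, u]: assignments with sample sizes (i, j) achieving U = u;
    # Gaussian-binomial recurrence c(i,j) = c(i-1,j) + q^i c(i,j-1)
    size = n * m + 1
    c = np.zeros((n + 1, m + 1, size), dtype=float)
    c[0, :, 0] = 1.0
    c[:, 0, 0] = 1.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c[i, j] = c[i - 1, j]
            c[i, j, i:] += c[i, j - 1, : size - i]
    return c[n, m]


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], n_comparisons: int = 1
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Midranks handle ties.  For untied data with ``n*m <= 400`` the p-value
    comes from the exact null distribution (full enumeration); otherwise
    from the normal approximation with tie-corrected variance and a
    continuity correction.  ``statistic`` is U for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    rank_sum_x = float(ranks[:n].sum())
    u = rank_sum_x - n * (n + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if not has_ties and n * m <= EXACT_LIMIT:
        counts = _exact_u_counts(n, m)
        total = counts.sum()
        ui = int(round(u))
        cdf = counts[: ui + 1].sum() / total
        sf = counts[ui:].sum() / total  # P(U >= u)
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "exact"
    else:
        N = n + m
        mean = n * m / 2.0
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1.0)))
        var = n * m / 12.0 * ((N + 1.0) - tie_term)
        if var <= 0:  # all values identical
            p = 1.0
        else:
            z = (abs(u - mean) - 0.5) / np.sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * float(_spstats.norm.sf(z)))
        method = "normal"
    return TestResult(
        statistic=float(u),
        p_raw=p,
        p_adjusted=min(1.0, n_comparisons * p),
        n_comparisons=n_comparisons,
        method=method,
    )


def bonferroni_adjust(
    pvals: Sequence[float], m: int | None = None
) -> np.ndarray:
    """Bonferroni-corrected p-values: min(1, m * p).

    ``m`` defaults to the number of p-values and must be at least that.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of p-values")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _split_by_label(
    values: Sequence[float], labels: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    mask = labels.astype(bool)
    cases, controls = values[mask], values[~mask]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def auc(values: Sequence[float], labels: Sequence) -> float:
    """Area under the ROC curve (cases score higher convention).

    Equals the pairwise concordance probability
    (#{case > control} + 0.5 #{case = control}) / (n_case * n_control),
    computed via midranks in O(n log n).  Values below 0.5 are reported
    as-is, never flipped.
    """
    cases, controls = _split_by_label(values, labels)
    pooled = np.concatenate([cases, controls])
    ranks = _midranks(pooled)
    u = ranks[: cases.size].sum() - cases.size * (cases.size + 1) / 2.0
    return float(u / (cases.size * controls.size))


def roc_points(values: Sequence[float], labels: Sequence) -> RocCurve:
    """Empirical ROC curve over all distinct score thresholds.

    Labels are truthy for cases; the predicted-positive rule is
    ``score >= threshold``.  Endpoints (0,0) and (1,1) are always present
    and the stored AUC is the trapezoidal area.
    """
    cases, controls = _split_by_label(values, labels)
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for thr in thresholds:
        tpr.append(float((cases >= thr).mean()))
        fpr.append(float((controls >= thr).mean()))
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        tpr.append(1.0)
        fpr.append(1.0)
    fpr_arr, tpr_arr = np.asarray(fpr), np.asarray(tpr)
    area = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocCurve(fpr=fpr_arr, tpr=tpr_arr, auc=area)


# ---------------------------------------------------------------------------
# correlation, box summary
# ---------------------------------------------------------------------------

def pearson_r(
    x: Sequence[float], y: Sequence[float], with_p: bool = False
) -> float | tuple[float, float]:
    """Pearson product-moment correlation (optionally with two-sided p).

    The p-value uses the t transform r*sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom.  Constant input raises (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("samples must have equal length >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined for constant input")
    r = float(xd @ yd) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if not with_p:
        return r
    n = x.size
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(_spstats.t.sf(abs(t), df=n - 2))
    return r, p


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Five-number box-plot summary with 1.5x-IQR whiskers.

    Quartiles use linear interpolation between order statistics; each
    whisker is the most extreme observation inside the corresponding
    Tukey fence.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
    )


# ---------------------------------------------------------------------------
# cohort-level convenience
# ---------------------------------------------------------------------------

def compare_groups(
    ds: BiomarkerDataset, pairs: Sequence[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Pairwise rank-sum tests with Bonferroni correction across pairs.

    ``pairs`` defaults to all unordered group pairs in dataset order; the
    correction factor m is the number of pairs tested.
    """
    groups = ds.groups
    if pairs is None:
        pairs = [
            (groups[i], groups[j])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        ]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        res = rank_sum_test(ds.group_values(a), ds.group_values(b), n_comparisons=m)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": ds.group_values(a).size,
                "n_b": ds.group_values(b).size,
                "U": res.statistic,
                "p_raw": res.p_raw,
                "p_bonferroni": res.p_adjusted,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
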