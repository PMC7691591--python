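"""Exact small-sample comparison machinery for the group endpoints.

With five subjects in one group and seven in the other, all
C(12, 5) = 792 group assignments can be enumerated, so both the
Wilcoxon rank-sum test and the curve permutation test are computed
exactly rather than by asymptotics or sampling.  Effect sizes use the
pooled standard deviation; the family of seven endpoint p-values is
adjusted with the Benjamini-Hochberg step-up procedure (FDR 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .endpoints import ENDPOINT_LABELS, ENDPOINT_TRANSFORMS, EndpointRecord


@dataclass(frozen=True)
class ComparisonRow:
    """One endpoint's group comparison: the columns of the summary table."""

    endpoint: str
    transform: str
    w_statistic: float
    p_value: float
    p_adjusted: float
    means_difference: float
    pooled_sd: float
    effect_size: float
    n_x: int
    n_y: int


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney count: pairs with x_i > y_j, half credit for ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _assignment_matrix(n: int, k: int) -> np.ndarray:
    """Boolean (C(n,k), n) matrix, one row per k-subset of range(n)."""
    rows = np.zeros((comb(n, k), n), dtype=bool)
    for r, idx in enumerate(combinations(range(n), k)):
        rows[r, list(idx)] = True
    return rows


def wilcoxon_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Wilcoxon rank-sum test by full enumeration.

    ``W`` is the Mann-Whitney form of the rank-sum statistic: the number
    of pairs with ``x_i > y_j`` (ties counted half, i.e. mid-ranks).
    The p-value enumerates all C(n_x + n_y, n_x) assignments of the
    pooled observations; two-sided is twice the smaller tail
    (observation included), capped at 1.  At complete separation with
    n = (5, 7) this gives W = 35 and p = 2/792.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n, k = pooled.size, x.size
    w_obs = _u_statistic(x, y)

    assign = _assignment_matrix(n, k)
    # U for every assignment: rank-sum of the selected subset minus k(k+1)/2
    ranks = pd.Series(pooled).rank().to_numpy()  # mid-ranks for ties
    rank_sums = assign @ ranks
    u_all = rank_sums - k * (k + 1) / 2.0
    tol = 1e-9
    upper = np.mean(u_all >= w_obs - tol)
    lower = np.mean(u_all <= w_obs + tol)
    p = min(1.0, 2.0 * min(upper, lower))
    return w_obs, float(p)


def pooled_effect_size(x, y) -> tuple[float, float, float]:
    """Means difference, pooled SD and standardized effect size |dx|/s_p.

    s_p^2 = ((n_x - 1) s_x^2 + (n_y - 1) s_y^2) / (n_x + n_y - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx + ny < 3:
        raise ValueError("need at least 3 observations in total")
    diff = float(x.mean() - y.mean())
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    sp = float(np.sqrt(sp2))
    return diff, sp, abs(diff) / sp


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class GroupCurves:
    """Per-subject curves on a shared grid (rows = subjects)."""

    grid: np.ndarray
    curves: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if curves.shape[1] != grid.size:
            raise ValueError("curves must share the grid length")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "curves", curves)

    @property
    def n(self) -> int:
        return self.curves.shape[0]


def dwell_proportion_curve(d: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Proportion of session time spent within distance r of a place, r in grid."""
    d = np.asarray(d, dtype=float)
    return (d[None, :] < np.asarray(grid)[:, None]).mean(axis=1)


def curve_permutation_test(g1: GroupCurves, g2: GroupCurves,
                           statistic: str = "area") -> float:
    """Exact label-permutation test for a group difference between curves.

    Under the null the subjects' curves are exchangeable between groups,
    so the statistic — the integral over the grid of
    ``|mean_1(r) - mean_2(r)|`` ("area"), or its maximum ("max") — is
    referred to its full enumeration over all C(n1+n2, n1) label
    assignments.  p is the fraction of assignments with a statistic at
    least as large as the observed one (which is always included).
    """
    if g1.n < 2 or g2.n < 2:
        raise ValueError("need at least 2 curves per group")
    if g1.grid.size != g2.grid.size or not np.allclose(g1.grid, g2.grid):
        raise ValueError("curve grids do not match")
    allc = np.vstack([g1.curves, g2.curves])
    n, k = allc.shape[0], g1.n
    assign = _assignment_matrix(n, k)
    mean1 = assign @ allc / k
    mean2 = (~assign) @ allc / (n - k)
    gaps = np.abs(mean1 - mean2)
    if statistic == "area":
        stats = np.trapezoid(gaps, g1.grid, axis=1)
    elif statistic == "max":
        stats = gaps.max(axis=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    obs = stats[0]  # first row = identity assignment (combinations order)
    return float(np.mean(stats >= obs - 1e-12))


def compare_groups(records: list[EndpointRecord],
                   group_x: str = "TD", group_y: str = "NTD",
                   n_samples: int | None = None) -> list[ComparisonRow]:
    """Build the endpoint comparison table between two groups.

    Each endpoint is transformed per its table label (sqrt for rates,
    logit for proportions), tested with the exact Wilcoxon rank-sum
    test, summarized by the pooled-SD effect size, and the seven
    p-values are BH-adjusted as a family.  Sessions with an undefined
    endpoint are dropped pairwise with a warning.
    """
    groups = {r.group for r in records}
    if not {group_x, group_y} <= groups:
        raise ValueError(f"need both groups {group_x!r} and {group_y!r}; have {groups}")
    rows: list[dict] = []
    for label in ENDPOINT_LABELS:
        tf = ENDPOINT_TRANSFORMS[label]
        xs, ys = [], []
        dropped = 0
        for r in records:
            v = r.transformed(n_samples)[label]
            if np.isnan(v):
                dropped += 1
                continue
            (xs if r.group == group_x else ys).append(v)
        if dropped:
            warnings.warn(f"{label}: dropped {dropped} session(s) with undefined value",
                          UserWarning, stacklevel=2)
        x, y = np.asarray(xs), np.asarray(ys)
        w, p = wilcoxon_exact(x, y)
        try:
            diff, sp, es = pooled_effect_size(x, y)
        except ValueError:
            diff, sp, es = float(x.mean() - y.mean()), 0.0, np.nan
        rows.append(dict(endpoint=label, transform=tf, w_statistic=w, p_value=p,
                         means_difference=diff, pooled_sd=sp, effect_size=es,
                         n_x=len(x), n_y=len(y)))
    adj = bh_adjust([r["p_value"] for r in rows])
    return [ComparisonRow(p_adjusted=float(a), **r) for r, a in zip(rows, adj)]


def comparison_table(rows: list[ComparisonRow]) -> pd.DataFrame:
    """The comparison as a DataFrame mirroring the summary-table columns."""
    return pd.DataFrame([
        {
            "endpoint": r.endpoint,
            "transform": r.transform,
            "W": r.w_statistic,
            "p_value": r.p_value,
            "p_adjusted_bh": r.p_adjusted,
            "means_difference": r.means_difference,
            "pooled_sd": r.pooled_sd,
            "effect_size": r.effect_size,
        }
        for r in rows
    ])
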