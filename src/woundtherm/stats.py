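"""Rank-based comparison of textural features between healing classes.

Each of the 19 features is compared between unhealed and healed wounds with a
two-sided Mann-Whitney U test (the feature distributions are not normal), and
features are ranked by ascending p-value.  Effect sizes are reported both as
Cohen's d (conventional small/medium/large reading) and as the rank-biserial
correlation, which is the natural companion of a rank test.  A raw 0.05
significance rule is applied — no multiple-testing correction — and the
number of tests is carried in the report so users can apply their own.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .texture import FEATURE_NAMES

__all__ = [
    "FeatureTestResult",
    "mann_whitney_u",
    "effect_size",
    "rank_features",
    "results_frame",
]


@dataclass
class FeatureTestResult:
    feature: str
    u_statistic: float
    p_value: float
    effect_size: float
    rank_biserial: float
    significant: bool
    direction: Literal["unhealed>healed", "unhealed<healed", "none"] = "none"
    degenerate: bool = False


def _u_from_ranks(rank_sum_x: float, nx: int) -> float:
    """U for sample x from its rank sum (ranks over the pooled data)."""
    return rank_sum_x - nx * (nx + 1) / 2.0


@lru_cache(maxsize=32)
def _exact_u_distribution_no_ties(nx: int, ny: int) -> np.ndarray:
    """Null distribution of U (counts) for untied data, by the classic
    recursion over choosing nx of nx+ny distinct ranks."""
    # f[k][u] after considering the k largest... use DP over items:
    # each of the pooled positions is either in x or y; U = number of (x, y)
    # pairs with x-rank > y-rank.  Standard recurrence:
    # N(u; nx, ny) = N(u - ny; nx - 1, ny) + N(u; nx, ny - 1)
    max_u = nx * ny
    table = {}

    def count(a: int, b: int) -> np.ndarray:
        if (a, b) in table:
            return table[(a, b)]
        if a == 0 or b == 0:
            arr = np.zeros(max_u + 1)
            arr[0] = 1.0
            table[(a, b)] = arr
            return arr
        arr = np.zeros(max_u + 1)
        left = count(a - 1, b)
        right = count(a, b - 1)
        arr[b:] += left[: max_u + 1 - b]
        arr += right
        table[(a, b)] = arr
        return arr

    return count(nx, ny)


def _exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p via the permutation null of rank sums.

    Untied pooled data uses the closed-form U count recursion; tied data
    enumerates all assignments of the pooled values to the two groups.
    Two-sided p is twice the smaller tail, capped at 1.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = _u_from_ranks(float(ranks[:nx].sum()), nx)

    if len(np.unique(pooled)) == nx + ny:
        dist = _exact_u_distribution_no_ties(nx, ny)
        total = dist.sum()
        k = int(round(u_x))
        p_lo = dist[: k + 1].sum() / total
        p_hi = dist[k:].sum() / total
    else:
        us = np.empty(0)
        idx = range(nx + ny)
        u_list = [
            _u_from_ranks(float(ranks[list(comb)].sum()), nx)
            for comb in itertools.combinations(idx, nx)
        ]
        us = np.asarray(u_list)
        eps = 1e-9
        p_lo = float((us <= u_x + eps).mean())
        p_hi = float((us >= u_x - eps).mean())
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return u_x, p


def _normal_approx_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Gaussian approximation with continuity correction."""
    from scipy.stats import norm

    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = _u_from_ranks(float(ranks[:nx].sum()), nx)
    n = nx + ny
    mu = nx * ny / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_x, 1.0
    z = (abs(u_x - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return u_x, float(2.0 * norm.sf(z))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "normal_approx", "auto"] = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for sample x, p-value).

    ``exact`` enumerates the permutation null of rank sums (pooled size must
    be <= 20); ``normal_approx`` uses the tie-corrected Gaussian with
    continuity correction; ``auto`` picks exact when feasible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([x, y])).size == 1:
        # every value tied across both samples: no evidence either way
        return x.size * y.size / 2.0, 1.0
    if mode == "auto":
        mode = "exact" if x.size + y.size <= 20 else "normal_approx"
    if mode == "exact":
        if x.size + y.size > 20:
            raise ValueError("exact mode requires a pooled size <= 20")
        return _exact_p(x, y)
    if mode == "normal_approx":
        return _normal_approx_p(x, y)
    raise ValueError(f"unknown mode {mode!r}")


def effect_size(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["cohens_d", "rank_biserial"] = "cohens_d",
) -> float:
    """Signed effect size; positive when group x (unhealed) exceeds group y.

    ``cohens_d`` = (mean x - mean y) / pooled SD with n-1 variances;
    ``rank_biserial`` = 2U/(nx*ny) - 1 from the Mann-Whitney U of x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "cohens_d":
        if x.size < 2 or y.size < 2:
            raise ValueError("cohens_d needs >= 2 values per sample")
        nx, ny = x.size, y.size
        pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (
            nx + ny - 2
        )
        if pooled_var == 0:
            raise ValueError("zero pooled SD: degenerate input")
        return float((x.mean() - y.mean()) / np.sqrt(pooled_var))
    if method == "rank_biserial":
        ranks = rankdata(np.concatenate([x, y]))
        u_x = _u_from_ranks(float(ranks[: x.size].sum()), x.size)
        return float(2.0 * u_x / (x.size * y.size) - 1.0)
    raise ValueError(f"unknown method {method!r}")


def _one_per_subject(table: pd.DataFrame) -> pd.DataFrame:
    """Keep a single image per subject: first by (subject_id, filename)."""
    cols = [c for c in ("subject_id", "filename") if c in table.columns]
    return (
        table.sort_values(cols, kind="mergesort")
        .groupby("subject_id", sort=True)
        .head(1)
    )


def rank_features(
    table: pd.DataFrame,
    one_per_subject: bool = False,
    alpha: float = 0.05,
    mode: Literal["exact", "normal_approx", "auto"] = "auto",
) -> list[FeatureTestResult]:
    """Test every feature between classes and rank by ascending p-value.

    ``table`` must carry a ``label`` column with values healed/unhealed and
    the 19 feature columns.  The unhealed group is sample x throughout, so
    positive effect sizes mean unhealed > healed.
    """
    if one_per_subject:
        table = _one_per_subject(table)
    x_tab = table[table["label"] == "unhealed"]
    y_tab = table[table["label"] == "healed"]
    if len(x_tab) == 0 or len(y_tab) == 0:
        raise ValueError("both healing classes must be present")
    results = []
    for name in FEATURE_NAMES:
        x = x_tab[name].to_numpy(dtype=float)
        y = y_tab[name].to_numpy(dtype=float)
        u, p = mann_whitney_u(x, y, mode=mode)
        degenerate = np.unique(np.concatenate([x, y])).size == 1
        try:
            d = effect_size(x, y, "cohens_d")
        except ValueError:
            d = 0.0
        rb = effect_size(x, y, "rank_biserial")
        med_x, med_y = float(np.median(x)), float(np.median(y))
        if med_x > med_y:
            direction = "unhealed>healed"
        elif med_x < med_y:
            direction = "unhealed<healed"
        else:
            direction = "none"
        results.append(
            FeatureTestResult(
                feature=name,
                u_statistic=float(u),
                p_value=float(p),
                effect_size=float(d),
                rank_biserial=float(rb),
                significant=bool(p < alpha),
                direction=direction,
                degenerate=degenerate,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.feature))
    return results


def results_frame(results: Sequence[FeatureTestResult]) -> pd.DataFrame:
    """Tabular view of ranked test results, in ranking order."""
    return pd.DataFrame([r.__dict__ for r in results])
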