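"""Group comparisons: two-tailed Mann-Whitney tests, star labels, quartiles.

Distributions of per-cell metrics (area, circularity, aspect ratio, FA
counts) and per-FA edge distances are compared between (surface, time)
groups with the non-parametric two-tailed Mann-Whitney U test, assuming
neither normality nor equal variance.  Exact p-values come from the full
null distribution of U when the samples are small (n1*n2 <= 400) and
tie-free; otherwise the normal approximation with tie-corrected variance
and continuity correction is used.  Raw pairwise p-values are reported
(no multiple-testing correction by default); an optional Holm adjustment
is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "GroupComparison",
    "mann_whitney",
    "star_label",
    "quartile_summary",
    "compare_all_groups",
]

EXACT_MAX_PAIRS = 400


@dataclass(frozen=True)
class GroupSample:
    """One (surface, time) group's observations of a single metric."""

    label: tuple[str, str] | str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size < 1:
            raise ValueError("group must contain at least one observation")
        if not np.all(np.isfinite(v)):
            raise ValueError("group values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class GroupComparison:
    labels: tuple
    n1: int
    n2: int
    U: float
    p_two_sided: float
    stars: str
    method: str


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_pairs: int = EXACT_MAX_PAIRS,
    labels: tuple = ("x", "y"),
) -> GroupComparison:
    """Two-tailed Mann-Whitney U test.

    U is the statistic of ``x`` (number of (x, y) pairs with x > y, ties
    counting one half).  The exact null distribution is used when
    ``n1 * n2 <= exact_max_pairs`` and the pooled sample is tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size * y.size <= exact_max_pairs) and not has_ties
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    p = float(min(res.pvalue, 1.0))
    return GroupComparison(
        labels=labels,
        n1=int(x.size),
        n2=int(y.size),
        U=float(res.statistic),
        p_two_sided=p,
        stars=star_label(p),
        method="exact" if exact else "normal_approx_tie_corrected",
    )


def star_label(p: float) -> str:
    """Significance stars: ns for p >= 0.05, then *, **, *** by decade and
    **** for p <= 1e-4 (the four-star bound is inclusive)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def quartile_summary(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, Q2, Q3) by linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float(q1), float(q2), float(q3)


def compare_all_groups(
    samples: Sequence[GroupSample],
    holm: bool = False,
) -> pd.DataFrame:
    """All pairwise Mann-Whitney comparisons as a tidy table.

    One row per unordered group pair, with n, U, the two-sided p and its
    star label.  ``holm=True`` applies the Holm step-down adjustment and
    derives stars from the adjusted p-values; the default reports raw
    pairwise p-values.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for a, b in itertools.combinations(samples, 2):
        cmp = mann_whitney(a.values, b.values, labels=(a.label, b.label))
        rows.append(
            {
                "group_a": str(a.label),
                "group_b": str(b.label),
                "n_a": cmp.n1,
                "n_b": cmp.n2,
                "U": cmp.U,
                "p_two_sided": cmp.p_two_sided,
                "stars": cmp.stars,
                "method": cmp.method,
            }
        )
    table = pd.DataFrame(rows)
    if holm:
        p = table["p_two_sided"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        table["p_holm"] = adj
        table["stars"] = [star_label(q) for q in adj]
    return table
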