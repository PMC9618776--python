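"""Nonparametric group comparison: Mann-Whitney U, Kruskal-Wallis H and
Holm-Sidak step-down adjustment.

The test statistics and the exact Mann-Whitney null distribution are computed
here directly; scipy supplies only rank assignment and the reference normal /
chi-square distribution functions. Two-sided p-values follow the usual
convention of doubling the one-sided tail (capped at 1).

Significance stars follow the common figure-legend convention:
``*`` p < 0.05, ``**`` p < 0.01, ``***`` p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "ComparisonResult",
    "mann_whitney",
    "kruskal_wallis",
    "holm_sidak",
    "significance_stars",
    "compare_groups",
]

#: Largest combined sample size for which the exact U distribution is used.
EXACT_N_MAX = 20

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Star annotation for a p-value (``ns`` when p >= 0.05)."""
    for thresh, stars in STAR_THRESHOLDS:
        if p < thresh:
            return stars
    return "ns"


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank interleavings giving each U value (0..n1*n2).

    p(u; n1, n2) satisfies p(u; n1, n2) = p(u - n2; n1 - 1, n2) +
    p(u; n1, n2 - 1), the Gaussian binomial coefficient recurrence.
    """
    max_u = n1 * n2
    # table[j] = counts for (i, j) at current i, over u
    prev = [np.array([1.0]) for _ in range(n2 + 1)]  # i = 0: only u = 0
    for i in range(1, n1 + 1):
        cur: list[np.ndarray] = []
        for j in range(n2 + 1):
            size = i * j + 1
            arr = np.zeros(size)
            if j == 0:
                arr[0] = 1.0
            else:
                a = prev[j]  # (i-1, j), shifted by j
                arr[j : j + len(a)] += a
                b = cur[j - 1]  # (i, j-1)
                arr[: len(b)] += b
            cur.append(arr)
        prev = cur
    out = np.zeros(max_u + 1)
    arr = prev[n2]
    out[: len(arr)] = arr
    return out


def mann_whitney(
    x, y, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with ``U = min(U_x, U_y)`` where
    ``U_x = R_x - n_x(n_x+1)/2`` and ``R_x`` is the rank sum of ``x`` in the
    pooled sample (mid-ranks for ties).

    ``mode``:

    - ``"exact"``: exact p from the enumerated null distribution of U
      (tie-free data only).
    - ``"normal-approx"``: normal approximation with tie-corrected variance
      and a 0.5 continuity correction.
    - ``"auto"`` (default): exact when the combined sample size is at most 20
      and there are no ties, otherwise the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_x = ranks[:n1].sum()
    u_x = r_x - n1 * (n1 + 1) / 2.0
    u_y = n1 * n2 - u_x
    u = min(u_x, u_y)

    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return u, 1.0  # no separation at all

    if mode == "auto":
        mode = "exact" if (n1 + n2 <= EXACT_N_MAX and not has_ties) else "normal-approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free samples; use normal-approx")
        counts = _u_counts(n1, n2)
        p_one = counts[: int(u) + 1].sum() / counts.sum()
        return u, min(1.0, 2.0 * float(p_one))
    if mode != "normal-approx":
        raise ValueError(f"unknown mode {mode!r}")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var <= 0:
        return u, 1.0
    z = (u - mu + 0.5) / np.sqrt(var)  # continuity correction toward the mean
    return u, min(1.0, 2.0 * float(norm.cdf(z)))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H test across three or more groups.

    ``H = 12/(N(N+1)) * sum n_i (rbar_i - (N+1)/2)^2`` with the tie
    correction divisor ``1 - sum(t^3 - t)/(N^3 - N)``; the p-value comes from
    the chi-square distribution with k-1 degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("kruskal_wallis needs >= 3 groups; use mann_whitney for two")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    sizes = np.array([g.size for g in groups])
    n = int(sizes.sum())
    if n < 5:
        raise ValueError("total sample size must be >= 5")
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    grand = (n + 1) / 2.0
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - grand) ** 2
        start += g.size
    h *= 12.0 / (n * (n + 1))
    tie_div = 1.0 - _tie_term(pooled) / (n**3 - n)
    if tie_div <= 0:  # every pooled value identical
        return 0.0, 1.0
    h /= tie_div
    return float(h), float(chi2.sf(h, len(groups) - 1))


def holm_sidak(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    Sorted ascending, the i-th smallest of m raw p-values is adjusted to
    ``1 - (1 - p_(i))**(m - i + 1)``, then a running maximum enforces
    step-down monotonicity and values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class ComparisonResult:
    """Outcome of one two-group comparison (possibly within a family)."""

    group_a: str
    group_b: str
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    summaries: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def p_effective(self) -> float:
        return self.p_raw if self.p_adjusted is None else self.p_adjusted

    @property
    def stars(self) -> str:
        return significance_stars(self.p_effective)

    def __post_init__(self) -> None:
        if not 0 <= self.p_raw <= 1:
            raise ValueError("raw p outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


def _group_summary(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
        rows.append(
            {"group": name, "n": v.size, "mean": float(v.mean()), "sd": sd,
             "sem": sd / np.sqrt(v.size) if v.size > 1 else np.nan}
        )
    return pd.DataFrame(rows)


def compare_groups(
    table: pd.DataFrame,
    value: str,
    group: str,
    pairwise: bool = False,
    mode: str = "auto",
) -> list[ComparisonResult]:
    """Compare a measurement across the groups of a tidy table.

    Two groups: a single Mann-Whitney test. Three or more: a Kruskal-Wallis
    omnibus test; with ``pairwise=True``, all pairwise Mann-Whitney tests with
    Holm-Sidak adjusted p-values are appended.
    """
    if value not in table.columns or group not in table.columns:
        raise KeyError(f"columns {value!r}/{group!r} not both present")
    groups = {
        str(name): np.asarray(sub[value].dropna(), dtype=float)
        for name, sub in table.groupby(group, sort=True)
    }
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")
    summary = _group_summary(groups)

    if len(names) == 2:
        u, p = mann_whitney(groups[names[0]], groups[names[1]], mode=mode)
        return [ComparisonResult(names[0], names[1], "mann-whitney", u, p, None, summary)]

    h, p = kruskal_wallis([groups[n] for n in names])
    results = [ComparisonResult("all", "all", "kruskal-wallis", h, p, None, summary)]
    if pairwise:
        pairs = list(combinations(names, 2))
        raw = []
        stats = []
        for a, b in pairs:
            u, pr = mann_whitney(groups[a], groups[b], mode=mode)
            raw.append(pr)
            stats.append(u)
        adj = holm_sidak(raw)
        for (a, b), u, pr, pa in zip(pairs, stats, raw, adj):
            results.append(
                ComparisonResult(a, b, "mann-whitney", u, pr, float(pa), summary)
            )
    return results
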