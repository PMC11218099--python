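"""Rank-sum contrasts of genomic and phenotypic metrics against dual baselines.

Each focal group is compared against (a) every non-polar genome and (b)
its clade neighbours from the species tree.  The second baseline is the
phylogeny-aware control: a signal that survives it cannot be explained
by divergence of the whole clade.

The two-sample test is the Wilcoxon rank-sum (Mann-Whitney U) with
midranks for ties.  Small tie-free problems (n1 + n2 <= 12) are solved
exactly by enumerating all C(n1+n2, n1) rank assignments; larger or tied
problems use the normal approximation with tie and continuity
corrections.  The method actually used is recorded in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .phylo import GroupedPhylogeny

__all__ = [
    "RankSumResult",
    "ContrastResult",
    "rank_sum_test",
    "dual_contrast",
    "holm_adjust",
    "contrast_table",
]

EXACT_MAX_N = 12  # largest tie-free pooled sample solved by full enumeration


@dataclass
class RankSumResult:
    u: float  # U statistic of the first sample
    p: float
    method: str  # 'exact' or 'normal'
    alternative: str


def _exact_p(u_obs: float, n1: int, n2: int, alternative: str) -> float:
    """Exact p by enumeration of all rank assignments (tie-free ranks 1..n)."""
    n = n1 + n2
    shift = n1 * (n1 + 1) / 2.0
    us = [sum(c) - shift for c in combinations(range(1, n + 1), n1)]
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs + 1e-9) / total
    p_ge = sum(1 for u in us if u >= u_obs - 1e-9) / total
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_p(u_obs: float, n1: int, n2: int, ties: np.ndarray, alternative: str) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = ((ties**3 - ties).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    sd = math.sqrt(var)
    # Edgeworth kurtosis term: the U null is symmetric but platykurtic,
    # excess kurtosis -(6/5)(n1^2+n2^2+n1*n2+n1+n2)/(n1*n2*(n+1)) tie-free
    g2 = -(6.0 / 5.0) * (n1 * n1 + n2 * n2 + n1 * n2 + n1 + n2) / (n1 * n2 * (n + 1))

    def _edgeworth_tail(z: float, upper: bool) -> float:
        base = norm.sf(z) if upper else norm.cdf(z)
        corr = norm.pdf(z) * (g2 / 24.0) * (z**3 - 3 * z)
        return float(min(1.0, max(0.0, base + corr if upper else base - corr)))

    # continuity correction of 1/2 toward the null mean
    p_greater = _edgeworth_tail((u_obs - mu - 0.5) / sd, upper=True)
    p_less = _edgeworth_tail((u_obs - mu + 0.5) / sd, upper=False)
    if alternative == "less":
        return float(p_less)
    if alternative == "greater":
        return float(p_greater)
    return float(min(1.0, 2.0 * min(p_less, p_greater)))


def rank_sum_test(x, y, alternative: str = "two_sided") -> RankSumResult:
    """Mann-Whitney U test of two independent samples.

    Returns the U statistic of ``x`` (number of (x, y) pairs with x > y,
    counting ties half) and the p-value under the chosen alternative.
    """
    if alternative not in {"two_sided", "less", "greater"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if not has_ties and n1 + n2 <= EXACT_MAX_N:
        return RankSumResult(u_obs, _exact_p(u_obs, n1, n2, alternative), "exact", alternative)
    return RankSumResult(
        u_obs, _normal_p(u_obs, n1, n2, tie_counts.astype(float), alternative), "normal", alternative
    )


@dataclass
class ContrastResult:
    """One focal-group-vs-baseline comparison of one metric."""

    focal_group: str
    metric: str
    baseline: str  # 'all_nonpolar' or 'clade_neighbours'
    n_focal: int
    n_baseline: int
    statistic_u: float
    p_two_sided: float
    direction: str  # 'decrease', 'increase' or 'none'
    significant: bool
    alpha: float
    method: str = ""
    n_missing: int = 0
    available: bool = True
    unavailable_reason: str = ""

    @property
    def stars(self) -> str:
        if not self.available:
            return "NA"
        if self.p_two_sided < 0.01:
            return "**"
        if self.p_two_sided < 0.05:
            return "*"
        return "NS"


def _unavailable(focal_group, metric, baseline, alpha, reason) -> ContrastResult:
    return ContrastResult(
        focal_group, metric, baseline, 0, 0, math.nan, math.nan, "none", False, alpha,
        available=False, unavailable_reason=reason,
    )


def _one_contrast(
    values: pd.Series, focal_ids, baseline_ids, focal_group, metric, baseline, alpha, tested_direction
) -> ContrastResult:
    fx = values.reindex(sorted(focal_ids))
    bx = values.reindex(sorted(baseline_ids))
    n_missing = int(fx.isna().sum() + bx.isna().sum())
    fx = fx.dropna()
    bx = bx.dropna()
    if fx.empty or bx.empty:
        return _unavailable(focal_group, metric, baseline, alpha, "no observations on one side")
    res = rank_sum_test(fx.to_numpy(), bx.to_numpy(), "two_sided")
    mf, mb = float(fx.median()), float(bx.median())
    direction = "decrease" if mf < mb else ("increase" if mf > mb else "none")
    significant = (res.p < alpha) and (
        direction == tested_direction if tested_direction else direction != "none"
    )
    return ContrastResult(
        focal_group, metric, baseline, int(fx.size), int(bx.size),
        res.u, res.p, direction, significant, alpha,
        method=res.method, n_missing=n_missing,
    )


def dual_contrast(
    metrics: pd.DataFrame,
    phylogeny: GroupedPhylogeny,
    focal_group: str,
    metric_name: str,
    alpha: float = 0.05,
    tested_direction: str = "decrease",
    neighbour_override: list[str] | None = None,
    min_neighbours: int = 1,
) -> tuple[ContrastResult, ContrastResult]:
    """(focal vs all non-polar, focal vs clade neighbours) for one metric.

    ``metrics`` is indexed by genome_id.  Genomes with a missing metric
    are excluded from the test and counted in ``n_missing``.  When the
    neighbour walk finds nobody, the second contrast is returned flagged
    unavailable rather than silently dropped.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if metric_name not in metrics.columns:
        raise ValueError(f"metric {metric_name!r} not in table")
    focal_ids = phylogeny.members(focal_group)
    if not focal_ids:
        raise ValueError(f"focal group {focal_group!r} is empty")
    values = metrics[metric_name]
    nonpolar = phylogeny.members("nonpolar")
    vs_all = _one_contrast(
        values, focal_ids, nonpolar, focal_group, metric_name, "all_nonpolar", alpha, tested_direction
    )
    nbs = phylogeny.neighbours_of(focal_group, min_neighbours=min_neighbours, override=neighbour_override)
    if nbs.none_found:
        vs_nb = _unavailable(
            focal_group, metric_name, "clade_neighbours", alpha, "no clade neighbours found"
        )
    else:
        vs_nb = _one_contrast(
            values, focal_ids, nbs.neighbour_ids, focal_group, metric_name,
            "clade_neighbours", alpha, tested_direction,
        )
    return vs_all, vs_nb


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default in contrasts)."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def contrast_table(results: list[ContrastResult]) -> pd.DataFrame:
    """Flatten contrast results for TSV output."""
    return pd.DataFrame(
        [
            {
                "focal_group": r.focal_group,
                "metric": r.metric,
                "baseline": r.baseline,
                "n_focal": r.n_focal,
                "n_baseline": r.n_baseline,
                "U": r.statistic_u,
                "p": r.p_two_sided,
                "direction": r.direction,
                "significant": r.significant,
                "stars": r.stars,
                "method": r.method,
                "n_missing": r.n_missing,
                "available": r.available,
            }
            for r in results
        ]
    )
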