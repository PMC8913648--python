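"""Comparison statistics used throughout the pipeline.

Self-contained implementations of the group-comparison tests the analysis
relies on: two-sided Fisher exact, two-sided Wilcoxon rank-sum (exact by
enumeration for small samples without ties, normal approximation with tie and
continuity corrections otherwise), Kruskal-Wallis with Dunn's pairwise
post-hoc comparisons (Holm-adjusted by default), the two-group log-rank test
for survival curves, trapezoid area under a curve (body-mass trajectories),
and Pearson/Spearman correlation.  Distribution tails come from scipy;
test statistics are computed here so every convention (tie handling,
two-sidedness, adjustment) is explicit and desk-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "SurvivalRecord",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "kruskal_wallis_dunn",
    "logrank",
    "auc_trapezoid",
    "correlation",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple = ()
    adjustment: str = "none"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class SurvivalRecord:
    animal_id: str
    group: str
    time: float
    event: bool  # True = death observed, False = censored

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be non-negative")


def fisher_exact(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    With margins fixed, the table probability is hypergeometric in ``a``.  The
    two-sided p-value sums the probabilities of all tables at least as extreme
    as (probability no greater than) the observed one, with a 1e-12 relative
    tolerance for floating-point ties -- the common "sum of small tables"
    convention, no mid-p.
    """
    for v in (a, b, c, d):
        if not float(v).is_integer() or v < 0:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, cs1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return TestResult(np.nan, 1.0, "fisher_exact", (0, 0))
    dist = sps.hypergeom(n, r1, cs1)
    support = np.arange(max(0, r1 + cs1 - n), min(r1, cs1) + 1)
    probs = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    odds = np.inf if b * c == 0 and a * d > 0 else (
        np.nan if b * c == 0 else (a * d) / (b * c)
    )
    return TestResult(float(odds), min(1.0, p), "fisher_exact", (r1, c + d))


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all C(n+m, n) group labelings."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    w_obs = float(ranks[:n].sum())
    mu = n * (len(pooled) + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    total = comb(len(pooled), n)
    count = 0
    for idx in combinations(range(len(pooled)), n):
        w = float(ranks[list(idx)].sum())
        if abs(w - mu) >= dev_obs - 1e-9:
            count += 1
    return count / total


def wilcoxon_rank_sum(x, y, exact_limit: int = 20) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact by enumeration when n+m <= ``exact_limit`` and there are no ties;
    otherwise the normal approximation with tie correction and a 0.5
    continuity correction.  The statistic reported is the rank sum W of the
    first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, m = x.size, y.size
    w = float(ranks[:n].sum())
    has_ties = np.unique(pooled).size < pooled.size
    if n + m <= exact_limit and not has_ties:
        p = _rank_sum_exact_p(x, y)
        return TestResult(w, min(1.0, p), "wilcoxon_rank_sum_exact", (n, m))
    mu = n * (n + m + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / ((n + m) * (n + m - 1))
    var = n * m / 12.0 * ((n + m + 1) - tie_term)
    if var <= 0:
        return TestResult(w, 1.0, "wilcoxon_rank_sum_normal", (n, m))
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * sps.norm.sf(z)
    return TestResult(w, min(1.0, p), "wilcoxon_rank_sum_normal", (n, m))


def kruskal_wallis_dunn(groups, adjust: str = "holm") -> TestResult:
    """Kruskal-Wallis H test with Dunn's pairwise post-hoc comparisons.

    ``groups`` is a sequence of samples.  H uses the tie correction; its
    p-value is chi-squared with g-1 df.  Dunn z statistics use pooled ranks
    with the tie-corrected variance; pairwise p-values are Holm-adjusted by
    default ("none" and "bh" are also accepted).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([g.size for g in groups])
    if sizes.min() < 1 or sizes.sum() < 2:
        raise ValueError("need at least 2 observations and no empty group")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    if tie_counts.size == 1:  # all values identical
        return TestResult(0.0, 1.0, "kruskal_wallis", tuple(sizes))
    bounds = np.cumsum(sizes)
    rank_sums = [ranks[s - g.size: s].sum() for g, s in zip(groups, bounds)]
    h = 12.0 / (n * (n + 1)) * sum(
        rs**2 / g.size for rs, g in zip(rank_sums, groups)
    ) - 3 * (n + 1)
    tie_c = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    h /= tie_c
    p = float(sps.chi2.sf(h, len(groups) - 1))

    mean_ranks = [rs / g.size for rs, g in zip(rank_sums, groups)]
    var_base = n * (n + 1) / 12.0 - (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    pairs, zvals, praw = [], [], []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        pairs.append((i, j))
        zvals.append(float(z))
        praw.append(float(2.0 * sps.norm.sf(abs(z))))
    padj = _adjust_p(np.array(praw), adjust)
    dunn = pd.DataFrame(
        {"group_i": [p_[0] for p_ in pairs], "group_j": [p_[1] for p_ in pairs],
         "z": zvals, "p_raw": praw, "p_adj": padj}
    )
    return TestResult(float(h), p, "kruskal_wallis_dunn", tuple(int(s) for s in sizes),
                      adjustment=adjust, extra={"dunn": dunn})


def _adjust_p(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p.copy()
    if method == "holm":
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        return adj
    if method == "bh":
        from .diffabund import bh_fdr

        return bh_fdr(p)
    raise ValueError(f"unknown adjustment {method!r}")


def logrank(records) -> TestResult:
    """Two-group log-rank test.

    At each distinct event time the observed deaths in group 1 are compared
    with the hypergeometric expectation given the numbers at risk; the
    chi-squared statistic (O-E)^2/V with 1 df gives the p-value.
    """
    recs = list(records)
    groups = sorted({r.group for r in recs})
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    if not any(r.event for r in recs):
        raise ValueError("no events observed")
    g1 = groups[0]
    times = np.array([r.time for r in recs])
    events = np.array([r.event for r in recs])
    in1 = np.array([r.group == g1 for r in recs])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d_tot = int((events & (times == t)).sum())
        d1 = int((events & (times == t) & in1).sum())
        o_minus_e += d1 - d_tot * n1 / n_tot
        if n_tot > 1:
            var += d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    if var == 0:
        return TestResult(0.0, 1.0, "logrank", (int(in1.sum()), int((~in1).sum())))
    chi2 = o_minus_e**2 / var
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult(float(chi2), p, "logrank", (int(in1.sum()), int((~in1).sum())))


def auc_trapezoid(t, y) -> float:
    """Trapezoid-rule area under a sampled curve over its observed span."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    if (np.diff(t) <= 0).any():
        raise ValueError("time must be strictly increasing")
    return float(np.trapezoid(y, t))


def correlation(x, y, method: str = "pearson") -> float:
    """Pearson product-moment or Spearman rank correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 values")
    if method == "spearman":
        x, y = sps.rankdata(x), sps.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero variance input")
    return float((xc * yc).sum() / denom)
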