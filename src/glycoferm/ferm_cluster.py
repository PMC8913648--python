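"""Clustering of glycans into fermentation groups.

The twelve kinetic descriptors per glycan are Z-scored column-wise (subtract
the mean across glycans, divide by the standard deviation), hierarchically
clustered with the Manhattan distance and complete linkage, and the number of
groups is chosen by the elbow of the within-cluster sum-of-squares curve over
tree cuts.  Per-group mean +/- SD kinetic curves and Fisher-exact enrichment
of compound classes (synthetic vs reference glycans) within groups summarize
the result.

The agglomeration is implemented here rather than delegated so that the tie
rule is fully specified: at equal dissimilarity the merge with the lowest
(i, j) cluster-index pair wins, which makes the tree deterministic given the
row order of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import fisher_exact

__all__ = [
    "MergeTree",
    "ClusterAssignment",
    "zscore",
    "hcluster",
    "wcss_for_cuts",
    "select_k_elbow",
    "cut_tree",
    "group_curves",
    "class_enrichment",
]


@dataclass(frozen=True)
class MergeTree:
    """Agglomerative merge tree.

    ``merges[m] = (a, b, height, size)``: clusters ``a`` and ``b`` (original
    leaves are 0..n-1, the cluster created by merge m gets id n+m) merge at
    the given dissimilarity into a cluster of ``size`` leaves.  Complete
    linkage guarantees heights are non-decreasing along merges.
    """

    n_leaves: int
    merges: tuple

    def to_linkage(self) -> np.ndarray:
        """SciPy-style (n-1, 4) linkage matrix for export/plotting."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat partition: ``labels[i]`` is the group (1..k) of item i."""

    labels: np.ndarray
    k: int
    ids: tuple | None = None

    def as_series(self) -> pd.Series:
        idx = list(self.ids) if self.ids is not None else range(len(self.labels))
        return pd.Series(self.labels, index=idx, name="group")


def zscore(matrix, ddof: int = 1):
    """Column-standardize a descriptor matrix (mean 0, SD 1 per column).

    Sample (n-1) SD by default, matching the usual R ``scale`` convention.
    A constant column has an undefined Z-score and raises an error naming it.
    """
    df = pd.DataFrame(matrix).astype(float)
    if len(df) < 2:
        raise ValueError("need at least 2 rows to Z-score")
    sd = df.std(ddof=ddof)
    const = sd[~(sd > 0)].index.tolist()
    if const:
        raise ValueError(f"constant column(s) have undefined Z-scores: {const}")
    out = (df - df.mean()) / sd
    return out if isinstance(matrix, pd.DataFrame) else out.to_numpy()


def _pairwise(x: np.ndarray, metric: str) -> np.ndarray:
    if metric == "manhattan":
        return np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    if metric == "euclidean":
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
        return np.sqrt(d2)
    raise ValueError(f"unknown metric {metric!r}")


def hcluster(matrix, metric: str = "manhattan", linkage: str = "complete") -> MergeTree:
    """Agglomerative clustering with complete linkage.

    Uses the Lance-Williams update for complete linkage (inter-cluster
    dissimilarity = max pairwise distance).  Ties are broken toward the
    lowest (i, j) cluster-id pair, so the tree is deterministic.
    """
    if linkage != "complete":
        raise ValueError("only complete linkage is supported")
    x = np.asarray(pd.DataFrame(matrix).to_numpy(), dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.isfinite(x).all():
        raise ValueError("matrix contains NaN or infinite values")
    n = x.shape[0]
    d = _pairwise(x, metric)

    active: dict[int, int] = {i: i for i in range(n)}  # cluster id -> row in d
    sizes = {i: 1 for i in range(n)}
    merges = []
    for m in range(n - 1):
        ids = sorted(active)
        best = None
        for ii, a in enumerate(ids):
            ra = active[a]
            for b in ids[ii + 1:]:
                h = d[ra, active[b]]
                # strict <: at exactly equal heights the lowest (a, b) pair,
                # visited first, wins
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        ra, rb = active[a], active[b]
        # complete linkage: new dissimilarity is the max to either member
        d[ra, :] = np.maximum(d[ra, :], d[rb, :])
        d[:, ra] = d[ra, :]
        d[ra, ra] = 0.0
        new_id = n + m
        del active[a], active[b]
        active[new_id] = ra
        sizes[new_id] = sizes.pop(a) + sizes.pop(b)
        merges.append((a, b, float(h), sizes[new_id]))
    return MergeTree(n_leaves=n, merges=tuple(merges))


def cut_tree(tree: MergeTree, k: int, ids=None) -> ClusterAssignment:
    """Cut the merge tree into ``k`` flat groups.

    The k-1 highest (last) merges are undone.  Group labels 1..k are assigned
    by decreasing group size, ties by first occurrence in row order.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    parent = list(range(n + len(tree.merges)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for m, (a, b, _h, _s) in enumerate(tree.merges[: n - k]):
        parent[find(a)] = parent[find(b)] = n + m
    roots = [find(i) for i in range(n)]
    # order groups by size desc, then by first occurrence
    order: dict[int, int] = {}
    counts: dict[int, int] = {}
    for i, r in enumerate(roots):
        counts[r] = counts.get(r, 0) + 1
        order.setdefault(r, i)
    ranked = sorted(counts, key=lambda r: (-counts[r], order[r]))
    relabel = {r: g + 1 for g, r in enumerate(ranked)}
    labels = np.array([relabel[r] for r in roots], dtype=int)
    return ClusterAssignment(labels=labels, k=k, ids=tuple(ids) if ids is not None else None)


def wcss_for_cuts(matrix, tree: MergeTree, kmax: int = 12) -> list[tuple[int, float]]:
    """Within-cluster sum of squares (Euclidean, in the given feature space)
    for tree cuts at k = 1..kmax."""
    x = np.asarray(pd.DataFrame(matrix).to_numpy(), dtype=float)
    kmax = min(kmax, tree.n_leaves)
    out = []
    for k in range(1, kmax + 1):
        labels = cut_tree(tree, k).labels
        w = 0.0
        for g in np.unique(labels):
            sub = x[labels == g]
            w += float(((sub - sub.mean(axis=0)) ** 2).sum())
        out.append((k, w))
    return out


def select_k_elbow(wcss_curve) -> int:
    """Pick k at the elbow of the WCSS curve (max chord distance).

    The elbow is operationalized kneedle-style: the k whose (k, WCSS) point
    is farthest (perpendicular distance) from the chord joining the first and
    last points of the curve.  Ties, including an exactly linear curve where
    every distance is 0, resolve to the smaller k.
    """
    pts = sorted((int(k), float(w)) for k, w in wcss_curve)
    if len(pts) < 2:
        return pts[0][0] if pts else 1
    ws = [w for _, w in pts]
    if any(ws[i + 1] > ws[i] * (1 + 1e-9) + 1e-9 for i in range(len(ws) - 1)):
        import warnings

        warnings.warn("WCSS curve is not non-increasing; clustering may be unstable")
    k1, w1 = pts[0]
    k2, w2 = pts[-1]
    chord = np.array([k2 - k1, w2 - w1], dtype=float)
    norm = np.hypot(*chord)
    if norm == 0:
        return k1
    best_k, best_d = k1, -1.0
    for k, w in pts:
        v = np.array([k - k1, w - w1], dtype=float)
        dist = abs(chord[0] * v[1] - chord[1] * v[0]) / norm
        if dist > best_d + 1e-12:
            best_k, best_d = k, dist
    return best_k


def group_curves(assignment: ClusterAssignment, plate: pd.DataFrame, channel: str):
    """Per-group mean +/- SD kinetic curves.

    ``plate`` is a long-format table with columns glycan_id, replicate, time,
    channel, value.  Replicates are averaged per glycan first; the SD is then
    across member glycans at each timepoint.  Groups with a single member get
    SD 0 and a flag.
    """
    if assignment.ids is None:
        raise ValueError("assignment must carry glycan ids for curve summaries")
    sub = plate[plate["channel"] == channel]
    per_glycan = (
        sub.groupby(["glycan_id", "time"])["value"].mean().unstack("time")
    )
    missing = [g for g in assignment.ids if g not in per_glycan.index]
    if missing:
        raise ValueError(f"assigned glycans missing from plate: {missing}")
    out = {}
    lab = assignment.as_series()
    for g in sorted(set(lab)):
        members = per_glycan.loc[lab.index[lab == g]]
        flagged = len(members) < 2
        out[g] = pd.DataFrame(
            {
                "time": members.columns.to_numpy(dtype=float),
                "mean": members.mean(axis=0).to_numpy(),
                "sd": (np.zeros(members.shape[1]) if flagged
                       else members.std(axis=0, ddof=1).to_numpy()),
            }
        )
        out[g].attrs["singleton"] = flagged
    return out


def class_enrichment(assignment: ClusterAssignment, classes, adjust: bool = False):
    """Fisher-exact enrichment of each compound class within each group.

    For every (group, class) pair a 2x2 table (in group vs not) x (class vs
    not) is tested two-sided.  Returns a tidy DataFrame; optionally BH-adjusts
    p-values across all tests.
    """
    import warnings

    lab = assignment.as_series()
    cls = pd.Series(classes)
    cls.index = lab.index
    rows = []
    for g in sorted(set(lab)):
        in_g = lab == g
        for c in sorted(set(cls)):
            in_c = cls == c
            if not in_c.any():
                warnings.warn(f"class {c!r} is empty; skipped")
                continue
            a = int((in_g & in_c).sum())
            b = int((in_g & ~in_c).sum())
            c2 = int((~in_g & in_c).sum())
            d = int((~in_g & ~in_c).sum())
            res = fisher_exact(a, b, c2, d)
            rows.append({"group": g, "class": c, "a": a, "b": b, "c": c2, "d": d,
                         "odds_ratio": res.statistic, "p_value": res.p_value})
    out = pd.DataFrame(rows)
    if adjust and len(out):
        from .diffabund import bh_fdr

        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out
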