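"""Community composition analyses of fecal-culture metagenomics.

Replicate cultures are averaged per (glycan, donor), each glycan's mean
species profile is expressed as a difference versus the no-glycan control,
and glycans are grouped into taxonomic-response clusters by K-means on those
difference vectors (K chosen by the elbow of the within-cluster sum of
squares).  Ecological summaries are Shannon diversity (natural log), species
richness, Bray-Curtis dissimilarity and non-metric multidimensional scaling
(NMDS) of the Bray-Curtis matrix, scored by Kruskal stress-1.

K-means (Lloyd's algorithm with k-means++ seeding, best of several restarts
by WCSS) and the NMDS majorization loop (Guttman transform alternated with
isotonic regression of configuration distances on dissimilarity ranks) are
implemented here so their convergence contracts -- WCSS never increases
across Lloyd iterations, stress never increases within a run -- are
observable and tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .ferm_cluster import ClusterAssignment, select_k_elbow

__all__ = [
    "OrdinationResult",
    "average_replicates",
    "response_matrix",
    "kmeans_cluster",
    "shannon",
    "richness",
    "bray_curtis",
    "bray_curtis_matrix",
    "nmds",
]


def average_replicates(taxa: pd.DataFrame, meta: pd.DataFrame):
    """Mean relative abundance per (donor, glycan), renormalized to sum 1.

    Returns ``(taxa_mean, meta_mean)`` with one row per (donor, glycan).
    """
    if "replicate" not in meta.columns:
        raise ValueError("metadata must carry a replicate column")
    keys = [meta["donor_id"], meta["glycan_id"]]
    mean_ab = taxa.groupby(keys).mean()
    mean_ab = mean_ab.div(mean_ab.sum(axis=1), axis=0)
    meta_mean = (
        meta.groupby(["donor_id", "glycan_id"], as_index=False)
        .first()[["donor_id", "glycan_id", "compound_class"]]
    )
    meta_mean = meta_mean.set_index(
        pd.MultiIndex.from_frame(meta_mean[["donor_id", "glycan_id"]])
    ).loc[mean_ab.index].reset_index(drop=True)
    mean_ab = mean_ab.reset_index(drop=True)
    return mean_ab, meta_mean


def response_matrix(taxa_mean: pd.DataFrame, meta_mean: pd.DataFrame,
                    control_label: str = "none", per_donor: bool = False):
    """Per-taxon abundance differences relative to the no-glycan control.

    With ``per_donor=False`` (default) the result is glycans x taxa: mean
    abundance under the glycan (across donors) minus mean under control.
    With ``per_donor=True`` rows are (donor, glycan) pairs, each relative to
    that donor's own control.  Every row sums to ~0 (differences of two
    unit-sum compositions).
    """
    donors = meta_mean["donor_id"].unique()
    is_ctl = meta_mean["glycan_id"] == control_label
    for donor in donors:
        if not (is_ctl & (meta_mean["donor_id"] == donor)).any():
            raise ValueError(f"no control ({control_label!r}) samples for donor {donor!r}")
    if per_donor:
        rows, index = [], []
        for donor in donors:
            dmask = (meta_mean["donor_id"] == donor).to_numpy()
            ctl = taxa_mean[dmask & is_ctl.to_numpy()].mean()
            for glycan in meta_mean.loc[dmask, "glycan_id"].unique():
                gmask = dmask & (meta_mean["glycan_id"] == glycan).to_numpy()
                rows.append(taxa_mean[gmask].mean() - ctl)
                index.append((donor, glycan))
        return pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index))
    ctl = taxa_mean[is_ctl.to_numpy()].mean()
    out = {}
    for glycan in meta_mean["glycan_id"].unique():
        gmask = (meta_mean["glycan_id"] == glycan).to_numpy()
        out[glycan] = taxa_mean[gmask].mean() - ctl
    return pd.DataFrame(out).T


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(len(x))]]
    for _ in range(1, k):
        d2 = np.min(
            ((x[:, None, :] - np.array(centers)[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        total = d2.sum()
        if total == 0:
            centers.append(x[rng.integers(len(x))])
            continue
        centers.append(x[rng.choice(len(x), p=d2 / total)])
    return np.array(centers)


def _lloyd(x: np.ndarray, centers: np.ndarray, max_iter: int = 300, tol: float = 1e-12):
    wcss_path = []
    labels = None
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        wcss = float(d2[np.arange(len(x)), labels].sum())
        wcss_path.append(wcss)
        new_centers = centers.copy()
        for j in range(len(centers)):
            members = x[labels == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
        if np.allclose(new_centers, centers, atol=tol, rtol=0):
            break
        centers = new_centers
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    wcss = float(d2[np.arange(len(x)), labels].sum())
    wcss_path.append(wcss)
    return labels, centers, wcss, wcss_path


def kmeans_cluster(matrix, k="elbow", restarts: int = 25, seed: int = 0,
                   kmax: int = 12):
    """K-means taxonomic-response clustering (best of restarts by WCSS).

    ``k`` may be an integer or ``"elbow"``, in which case WCSS(k) for
    k = 1..kmax feeds the chord-distance elbow rule.  Returns
    ``(assignment, info)`` where info carries centers, wcss, the per-restart
    best WCSS path and (in elbow mode) the WCSS curve.
    """
    df = pd.DataFrame(matrix)
    x = df.to_numpy(dtype=float)
    n = len(x)
    rng = np.random.default_rng(seed)

    def run(k_):
        if not 1 <= k_ <= n:
            raise ValueError(f"k={k_} out of range [1, {n}]")
        best = None
        for _ in range(max(1, restarts)):
            centers0 = _kmeanspp_init(x, k_, rng)
            labels, centers, wcss, path = _lloyd(x, centers0)
            if best is None or wcss < best[2]:
                best = (labels, centers, wcss, path)
        return best

    info: dict = {}
    if k == "elbow":
        curve = []
        runs = {}
        for k_ in range(1, min(kmax, n) + 1):
            runs[k_] = run(k_)
            curve.append((k_, runs[k_][2]))
        k = select_k_elbow(curve)
        info["wcss_curve"] = curve
        labels, centers, wcss, path = runs[k]
    else:
        labels, centers, wcss, path = run(int(k))
    # relabel 1..k by cluster size desc, then first occurrence
    counts = {c: int((labels == c).sum()) for c in np.unique(labels)}
    first = {c: int(np.argmax(labels == c)) for c in counts}
    ranked = sorted(counts, key=lambda c: (-counts[c], first[c]))
    relabel = {c: g + 1 for g, c in enumerate(ranked)}
    labels = np.array([relabel[c] for c in labels], dtype=int)
    info.update({"centers": centers, "wcss": wcss, "wcss_path": path})
    return ClusterAssignment(labels=labels, k=int(k), ids=tuple(df.index)), info


def shannon(p) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log), 0 ln 0 := 0."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def richness(p, threshold: float = 0.0) -> int:
    """Number of taxa with abundance strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    p = np.asarray(p, dtype=float)
    return int((p > threshold).sum())


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(table) -> pd.DataFrame:
    """Square symmetric Bray-Curtis dissimilarity matrix over table rows."""
    df = pd.DataFrame(table)
    x = df.to_numpy(dtype=float)
    n = len(x)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(x[i], x[j])
    return pd.DataFrame(d, index=df.index, columns=df.index)


@dataclass(frozen=True)
class OrdinationResult:
    coords: np.ndarray       # samples x dims
    stress: float            # Kruskal stress-1 of the best run
    n_restarts: int
    converged: bool
    stress_path: tuple = ()  # stress sequence of the best run


def _nmds_single(d: np.ndarray, dims: int, rng: np.random.Generator,
                 max_iter: int, tol: float):
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    diss = d[iu]
    order = np.argsort(diss, kind="mergesort")
    iso = IsotonicRegression(increasing=True)
    x = rng.standard_normal((n, dims)) * np.std(diss)

    def config_dist(xc):
        return np.sqrt(((xc[:, None, :] - xc[None, :, :]) ** 2).sum(axis=2))

    def stress1(dist, dhat):
        denom = float((dist[iu] ** 2).sum())
        if denom == 0:
            return 0.0
        return float(np.sqrt(((dist[iu] - dhat) ** 2).sum() / denom))

    path = []
    best_x = x
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        dist = config_dist(x)
        dij = dist[iu]
        # monotone (isotonic) regression of distances on dissimilarity ranks
        dhat = np.empty_like(dij)
        dhat[order] = iso.fit_transform(np.arange(diss.size), dij[order])
        s = stress1(dist, dhat)
        if path and s > path[-1]:
            break  # only accept improving steps: recorded stress is monotone
        path.append(s)
        best_x = x
        if prev - s < tol:
            converged = True
            break
        prev = s
        # Guttman transform with disparities dhat
        dh = np.zeros((n, n))
        dh[iu] = dhat
        dh += dh.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dh / dist, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
        x -= x.mean(axis=0)
    return best_x, (path[-1] if path else 0.0), converged, tuple(path)


def nmds(dissimilarity, dims: int = 2, restarts: int = 20, seed: int = 0,
         tol: float = 1e-6, max_iter: int = 500) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Alternates isotonic regression of configuration distances on
    dissimilarity ranks with Guttman-transform configuration updates,
    minimizing Kruskal stress-1 = sqrt(sum (d - dhat)^2 / sum d^2).  The best
    of ``restarts`` random starts is returned; within a run the recorded
    stress sequence is non-increasing by construction.
    """
    d = np.asarray(pd.DataFrame(dissimilarity).to_numpy(), dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    n = d.shape[0]
    if n <= dims:
        # any configuration of <= dims+1 points can realize the ranks exactly
        max_iter = max(max_iter, 1000)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        x, s, conv, path = _nmds_single(d, dims, rng, max_iter, tol)
        if best is None or s < best.stress:
            best = OrdinationResult(coords=x, stress=s, n_restarts=restarts,
                                    converged=conv, stress_path=path)
    return best
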