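"""Cross-donor differential abundance of genera and CAZyme families.

For each feature (genus or CAZyme family) and each glycan treatment the
pipeline computes per-donor log2 fold changes of replicate-mean relative
abundance versus the donor's no-glycan control (with a pseudocount), and the
median log2FC across donors.  Significance comes from a linear mixed-effect
model fitted to rank-transformed abundances with glycan treatment as fixed
effect and subject (donor) as random intercept:

    rank_ij = b0 + b * treat_ij + u_j + e_ij,
    u_j ~ N(0, s_u^2),  e_ij ~ N(0, s_e^2)

The model is fitted by profiling the likelihood over the variance ratio
s_u^2/s_e^2 (a 1-D bounded optimization with closed-form GLS at each ratio),
REML for the reported estimates and full ML for the likelihood-ratio test of
b = 0 (chi-squared, 1 df).  Variance components are constrained >= 0.
P-values are Benjamini-Hochberg adjusted to control the false discovery
rate; the display filter additionally requires |median log2FC| > 1 on at
least one glycan, and retained feature profiles are hierarchically clustered
with Euclidean distance and complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

__all__ = [
    "LmmFit",
    "log2fc",
    "rank_transform",
    "fit_rank_lmm",
    "bh_fdr",
    "differential_abundance",
    "significant_features",
]


# ---------------------------------------------------------------- log2 FC


def log2fc(taxa: pd.DataFrame, meta: pd.DataFrame, control_label: str = "none",
           pseudocount: float = 1e-5) -> pd.DataFrame:
    """Per (feature, glycan, donor) log2 fold change vs the no-glycan control.

    ``taxa`` is samples x features (relative abundance), ``meta`` carries
    glycan_id, compound_class, donor_id, replicate per sample.  Abundances are
    replicate-averaged per (donor, glycan) first; the fold change is
    log2((a_trt + c) / (a_ctl + c)).  Returns a tidy frame with per-donor
    log2fc plus the cross-donor median and a detected_in_control flag.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mean_ab = taxa.groupby([meta["donor_id"], meta["glycan_id"]]).mean()
    donors = mean_ab.index.get_level_values(0).unique()
    rows = []
    for donor in donors:
        block = mean_ab.loc[donor]
        if control_label not in block.index:
            raise ValueError(f"donor {donor!r} has no control ({control_label!r}) samples")
        ctl = block.loc[control_label]
        for glycan in block.index:
            if glycan == control_label:
                continue
            fc = np.log2((block.loc[glycan] + pseudocount) / (ctl + pseudocount))
            for feat in taxa.columns:
                rows.append({
                    "feature": feat, "glycan": glycan, "donor": donor,
                    "log2fc": float(fc[feat]),
                    "detected_in_control": bool(ctl[feat] > 0),
                })
    out = pd.DataFrame(rows)
    med = out.groupby(["feature", "glycan"])["log2fc"].median().rename("median_log2fc")
    return out.merge(med, on=["feature", "glycan"])


def rank_transform(values) -> np.ndarray:
    """Ranks 1..n with average ranks for ties (per feature, across samples)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 samples to rank")
    return sps.rankdata(values)


# ---------------------------------------------------------------- rank LMM


@dataclass(frozen=True)
class LmmFit:
    beta: float        # treatment fixed effect on the rank scale
    intercept: float
    sigma_u2: float    # subject random-intercept variance
    sigma_e2: float    # residual variance
    p_value: float     # LRT against beta = 0 (chi2, 1 df)
    loglik_ml: float
    n_obs: int
    n_subjects: int


def _gls_profile(lam: float, y: np.ndarray, x: np.ndarray, idx: list, reml: bool):
    """Closed-form GLS and profiled -2 log-likelihood at variance ratio lam.

    V is block diagonal, V_j = I + lam * J for subject j; its inverse acts as
    v^-1 r = r - lam/(1 + n_j lam) * sum(r) within each block (Woodbury).
    """
    n, p = x.shape

    def vinv(a: np.ndarray) -> np.ndarray:
        out = a.astype(float).copy()
        for rows in idx:
            shrink = lam / (1.0 + len(rows) * lam)
            out[rows] -= shrink * a[rows].sum(axis=0)
        return out

    xtvx = x.T @ vinv(x)
    xtvy = x.T @ vinv(y)
    beta = np.linalg.solve(xtvx, xtvy)
    r = y - x @ beta
    quad = float(r @ vinv(r))
    logdet_v = sum(np.log1p(len(rows) * lam) for rows in idx)
    if reml:
        dof = n - p
        s2 = quad / dof
        sign, logdet_x = np.linalg.slogdet(xtvx)
        crit = dof * np.log(s2) + logdet_v + logdet_x + dof
    else:
        s2 = quad / n
        crit = n * np.log(2 * np.pi * s2) + logdet_v + n
    return crit, beta, s2


def _fit_lam(y, x, idx, reml):
    best = None
    for lam0 in (0.0, 0.01, 0.1, 1.0, 10.0, 100.0):
        c = _gls_profile(lam0, y, x, idx, reml)[0]
        if best is None or c < best[1]:
            best = (lam0, c)
    res = minimize_scalar(
        lambda u: _gls_profile(np.exp(u), y, x, idx, reml)[0],
        bracket=None, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    crit = float(res.fun)
    if best[1] < crit:  # boundary / grid point wins
        lam, crit = best
    c, beta, s2 = _gls_profile(lam, y, x, idx, reml)
    return lam, c, beta, s2


def fit_rank_lmm(ranks, treatment, subjects) -> LmmFit:
    """Random-intercept LMM of ranks on a treatment indicator.

    Estimates are REML; the p-value for the treatment effect is a
    likelihood-ratio test (full-ML fits of the full and treatment-free
    models, chi-squared with 1 df).  Requires >= 2 subjects, each observed
    under both treatment and control; a design where treatment is confounded
    with subject is rejected.
    """
    y = np.asarray(ranks, dtype=float)
    treat = np.asarray(treatment, dtype=float)
    subj = pd.Series(subjects)
    if not ((treat == 0) | (treat == 1)).all():
        raise ValueError("treatment must be a 0/1 indicator")
    if y.shape != treat.shape or len(subj) != y.size:
        raise ValueError("ranks, treatment and subjects must align")
    codes, uniq = pd.factorize(subj)
    if len(uniq) < 2:
        raise ValueError("need at least 2 subjects")
    idx = [np.flatnonzero(codes == j) for j in range(len(uniq))]
    for j, rows in enumerate(idx):
        tj = treat[rows]
        if tj.min() == tj.max():
            raise ValueError(
                f"subject {uniq[j]!r} lacks both treated and control observations "
                "(treatment confounded with subject)"
            )
    x = np.column_stack([np.ones_like(y), treat])

    lam_r, _, beta_r, s2_r = _fit_lam(y, x, idx, reml=True)
    _, crit_full, _, _ = _fit_lam(y, x, idx, reml=False)
    x0 = x[:, :1]
    _, crit_null, _, _ = _fit_lam(y, x0, idx, reml=False)
    lrt = max(0.0, crit_null - crit_full)  # crit is -2 loglik up to shared const
    p = float(sps.chi2.sf(lrt, 1))
    return LmmFit(
        beta=float(beta_r[1]), intercept=float(beta_r[0]),
        sigma_u2=float(lam_r * s2_r), sigma_e2=float(s2_r),
        p_value=p, loglik_ml=-0.5 * crit_full,
        n_obs=y.size, n_subjects=len(uniq),
    )


# ---------------------------------------------------------------- BH FDR


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------- pipeline


def differential_abundance(taxa: pd.DataFrame, meta: pd.DataFrame,
                           control_label: str = "none",
                           pseudocount: float = 1e-5) -> pd.DataFrame:
    """Full per-feature differential abundance analysis against control.

    Each glycan is tested against the no-glycan control in its own model
    (treatment indicator = that glycan vs control), one model per feature.
    Ranks are computed per feature across all samples entering that model.
    Q-values are BH-adjusted across features within each glycan.
    """
    fc = log2fc(taxa, meta, control_label, pseudocount)
    glycans = [g for g in meta["glycan_id"].unique() if g != control_label]
    rows = []
    for glycan in glycans:
        mask = meta["glycan_id"].isin([glycan, control_label]).to_numpy()
        treat = (meta.loc[mask, "glycan_id"] == glycan).to_numpy(dtype=float)
        subj = meta.loc[mask, "donor_id"].to_numpy()
        pvals = []
        for feat in taxa.columns:
            ranks = rank_transform(taxa.loc[mask, feat].to_numpy())
            fit = fit_rank_lmm(ranks, treat, subj)
            pvals.append(fit.p_value)
            rows.append({"feature": feat, "glycan": glycan,
                         "estimate": fit.beta, "p_value": fit.p_value})
        qs = bh_fdr(np.array(pvals))
        for r, q in zip(rows[-len(taxa.columns):], qs):
            r["q_value"] = float(q)
    res = pd.DataFrame(rows)
    med = fc.drop_duplicates(["feature", "glycan"])[
        ["feature", "glycan", "median_log2fc"]
    ]
    det = fc.groupby(["feature", "glycan"])["detected_in_control"].any().reset_index()
    return res.merge(med, on=["feature", "glycan"]).merge(det, on=["feature", "glycan"])


def significant_features(results: pd.DataFrame, alpha: float = 0.05,
                         fc_filter: float | None = 1.0):
    """Display filter and clustering of significant feature profiles.

    Keeps features with q < alpha on at least one glycan and, when
    ``fc_filter`` is set, |median log2FC| > fc_filter on at least one glycan.
    Returns ``(profiles, tree)``: the retained features x glycans median
    log2FC matrix and its Euclidean/complete-linkage merge tree (None when
    fewer than 2 features survive).
    """
    import warnings

    from .ferm_cluster import hcluster

    if results.empty:
        warnings.warn("empty result set; nothing to filter")
        return pd.DataFrame(), None
    prof = results.pivot_table(index="feature", columns="glycan",
                               values="median_log2fc")
    qmin = results.groupby("feature")["q_value"].min()
    keep = qmin[qmin < alpha].index
    if fc_filter is not None:
        keep = [f for f in keep if (prof.loc[f].abs() > fc_filter).any()]
    prof = prof.loc[sorted(keep)]
    if prof.empty:
        warnings.warn("no features pass the significance/fold-change filter")
        return prof, None
    tree = hcluster(prof, metric="euclidean", linkage="complete") if len(prof) > 1 else None
    return prof, tree
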