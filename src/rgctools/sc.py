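"""Compact scRNA-seq stage: QC, normalization, PCA, clustering, DEG, typing.

The pipeline mirrors the classic Seurat-v2-era workflow on an AnnData
container: cells with fewer than 300 detected genes are removed first, then
genes detected in fewer than 3 surviving cells; counts are LogNormalized to a
10^4 scale; dispersion-based highly variable genes feed a 10-component PCA
(after optional covariate regression and clipped unit-variance scaling);
clusters come from modularity optimisation on a kNN graph in PC space;
differential expression is a two-sided Wilcoxon rank-sum test with BH
adjustment, called significant at |log2FC| > 0.3 and adjusted p < 0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scanpy as scp
from anndata import AnnData
from scipy import sparse
from scipy import stats as sps

from .stats import benjamini_hochberg

__all__ = [
    "QCThresholds",
    "qc_filter",
    "lognormalize",
    "hvg_scale_pca",
    "cluster_cells",
    "wilcoxon_deg",
    "rank_sum_p",
    "annotate_and_compose",
]

EXACT_MAX_N = 12  # total group size up to which the rank-sum p is enumerated


@dataclass(frozen=True)
class QCThresholds:
    min_genes_per_cell: int = 300
    min_cells_per_gene: int = 3
    max_mito_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValueError("thresholds must be >= 0")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def qc_filter(adata: AnnData, thresholds: QCThresholds = QCThresholds()) -> AnnData:
    """Remove low-quality cells, then sparsely detected genes.

    "At least" thresholds are inclusive: a cell with exactly
    ``min_genes_per_cell`` detected genes survives. The order (cells first,
    then genes against the surviving cells) changes results and is fixed.
    Removal counts are stored in ``uns['qc']``.
    """
    adata = adata.copy()
    n_cells0, n_genes0 = adata.shape
    scp.pp.filter_cells(adata, min_genes=thresholds.min_genes_per_cell)
    if thresholds.max_mito_fraction is not None:
        mito = adata.var_names.str.lower().str.startswith("mt-")
        frac = _dense(adata[:, mito].X).sum(axis=1) / np.maximum(
            _dense(adata.X).sum(axis=1), 1
        )
        adata = adata[frac <= thresholds.max_mito_fraction].copy()
    scp.pp.filter_genes(adata, min_cells=thresholds.min_cells_per_gene)
    removed = {
        "cells_removed": n_cells0 - adata.n_obs,
        "genes_removed": n_genes0 - adata.n_vars,
    }
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError(f"QC removed everything: {removed}")
    adata.uns["qc"] = {**removed, "thresholds": thresholds.__dict__.copy()}
    return adata


def lognormalize(adata: AnnData, scale: float = 1e4) -> AnnData:
    """LogNormalize in place of X: ln(1 + count / cell_total * scale).

    Raw counts are kept in ``layers['counts']``. After the transform the
    per-cell sums of expm1(X) equal ``scale`` exactly.
    """
    adata = adata.copy()
    totals = _dense(adata.X).sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("zero-total cell encountered (run qc_filter first)")
    adata.layers["counts"] = adata.X.copy()
    scp.pp.normalize_total(adata, target_sum=scale)
    scp.pp.log1p(adata)
    adata.uns["lognormalize_scale"] = scale
    return adata


def hvg_scale_pca(
    adata: AnnData,
    n_pcs: int = 10,
    covariates: Optional[Sequence[str]] = None,
    n_top_genes: int = 500,
) -> AnnData:
    """Dispersion-based HVG selection, covariate regression, scaled PCA.

    Per-gene linear regression residuals against the named ``obs`` covariates
    replace the values before unit-variance scaling clipped at +/-10. The top
    ``n_pcs`` principal components are stored in ``obsm['X_pca']`` with a
    deterministic sign convention (the largest-magnitude loading of every
    component is positive).
    """
    adata = adata.copy()
    if adata.n_vars < n_pcs:
        raise ValueError("fewer genes than requested principal components")
    n_top = min(n_top_genes, adata.n_vars)
    scp.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_top)
    sub = adata[:, adata.var["highly_variable"]].copy()
    if sub.n_vars < n_pcs:
        sub = adata.copy()
    if covariates:
        scp.pp.regress_out(sub, keys=list(covariates))
    scp.pp.scale(sub, max_value=10)
    scp.tl.pca(sub, n_comps=n_pcs, svd_solver="arpack", random_state=0)
    emb = sub.obsm["X_pca"].copy()
    loadings = sub.varm["PCs"].copy()
    for c in range(n_pcs):
        peak = np.argmax(np.abs(loadings[:, c]))
        if loadings[peak, c] < 0:
            loadings[:, c] *= -1
            emb[:, c] *= -1
    adata.obsm["X_pca"] = emb
    adata.uns["pca"] = {
        "n_pcs": n_pcs,
        "hvg_method": "seurat-dispersion",
        "n_hvg": int(adata.var["highly_variable"].sum()),
        "covariates": list(covariates) if covariates else [],
    }
    return adata


def cluster_cells(
    adata: AnnData,
    resolution: float = 1.0,
    k: int = 20,
    seed: int = 0,
    key_added: str = "cluster",
) -> AnnData:
    """Modularity community detection (Leiden) on a kNN graph in PC space."""
    if adata.n_obs < k:
        raise ValueError(f"need at least k={k} cells to build the kNN graph")
    adata = adata.copy()
    scp.pp.neighbors(adata, n_neighbors=k, use_rep="X_pca", random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        scp.tl.leiden(adata, resolution=resolution, random_state=seed,
                      key_added=key_added)
    n_clusters = adata.obs[key_added].nunique()
    if adata.n_obs < 100 and n_clusters > 10:
        warnings.warn(
            f"{n_clusters} clusters from {adata.n_obs} cells: resolution "
            "probably too high"
        )
    return adata


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by enumerating every assignment of pooled values."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, n_a = pooled.size, x.size
    mu = n_a * (n + 1) / 2.0
    obs = abs(ranks[:n_a].sum() - mu)
    hits = 0
    total = comb(n, n_a)
    for idx in itertools.combinations(range(n), n_a):
        if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p value for one gene.

    Small pooled samples (n <= 12) are enumerated exactly over all
    assignments using midranks, so ties are handled; larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size + y.size <= EXACT_MAX_N:
        return _exact_rank_sum_p(x, y)
    return _asymptotic_rank_sum_p(x[None, :], y[None, :])[0]


def _asymptotic_rank_sum_p(X_a: np.ndarray, X_b: np.ndarray) -> np.ndarray:
    """Vectorised tie-corrected normal-approximation p, genes along axis 0."""
    n_a, n_b = X_a.shape[1], X_b.shape[1]
    n = n_a + n_b
    pooled = np.concatenate([X_a, X_b], axis=1)
    ranks = sps.rankdata(pooled, axis=1)
    w = ranks[:, :n_a].sum(axis=1)
    mu = n_a * (n + 1) / 2.0
    # tie correction: sum over tied groups of (t^3 - t) per gene
    srt = np.sort(pooled, axis=1)
    tie_term = np.zeros(pooled.shape[0])
    for g in range(pooled.shape[0]):
        _, counts = np.unique(srt[g], return_counts=True)
        tie_term[g] = np.sum(counts**3 - counts)
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    diff = np.abs(w - mu) - 0.5  # continuity correction
    diff = np.maximum(diff, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, diff / sigma, 0.0)
    return 2 * sps.norm.sf(z)


def wilcoxon_deg(
    adata: AnnData,
    group_key: str,
    group_a: str,
    group_b: str,
    log2fc_min: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell groups.

    Expects LogNormalized X. log2FC is computed on de-logged (expm1)
    normalized means with a pseudocount of 1; p values are BH-adjusted across
    all tested genes and the significant set is
    {adj_p < alpha and |log2fc| > log2fc_min}. Rows are sorted by adjusted p.
    """
    mask_a = np.asarray(adata.obs[group_key] == group_a)
    mask_b = np.asarray(adata.obs[group_key] == group_b)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must be nonempty")
    X = _dense(adata.X)
    X_a, X_b = X[mask_a].T, X[mask_b].T  # genes x cells
    n_a, n_b = X_a.shape[1], X_b.shape[1]
    if min(n_a, n_b) < 3:
        warnings.warn("group of size < 3: exact-enumeration p values used")
    if n_a + n_b <= EXACT_MAX_N or min(n_a, n_b) < 3:
        p = np.array([_exact_rank_sum_p(X_a[g], X_b[g]) for g in range(X.shape[1])])
    else:
        p = _asymptotic_rank_sum_p(X_a, X_b)
    mean_a = np.expm1(X_a).mean(axis=1)
    mean_b = np.expm1(X_b).mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    adj_p = benjamini_hochberg(np.clip(p, np.nextafter(0, 1), 1.0))
    records = pd.DataFrame(
        {
            "gene": adata.var_names,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj_p,
            "pct_a": (X_a > 0).mean(axis=1) * 100,
            "pct_b": (X_b > 0).mean(axis=1) * 100,
        }
    )
    records["significant"] = (records["adj_p"] < alpha) & (
        records["log2fc"].abs() > log2fc_min
    )
    records.attrs["log2fc_pseudocount"] = 1.0
    records.attrs["fc_scale"] = "expm1-normalized means"
    return records.sort_values("adj_p", kind="mergesort").reset_index(drop=True)


def annotate_and_compose(
    adata: AnnData,
    marker_sets: dict,
    cluster_key: str = "cluster",
    group_key: str = "group",
    margin: float = 0.05,
) -> tuple:
    """Assign cell types to clusters by marker expression; tabulate groups.

    Each cluster scores every type as the mean (over the type's marker genes
    present in the matrix) of the cluster-mean normalized expression, with
    each gene rescaled by its maximum cluster mean so genes contribute
    comparably. The cluster takes the top-scoring type unless the runner-up
    is within ``margin`` (tie -> "unassigned"). Returns (calls DataFrame,
    group x type percentage table).
    """
    X = _dense(adata.X)
    clusters = adata.obs[cluster_key].astype(str)
    cluster_ids = sorted(clusters.unique())
    cluster_means = pd.DataFrame(
        {cid: X[np.asarray(clusters == cid)].mean(axis=0) for cid in cluster_ids},
        index=adata.var_names,
    )
    usable = {}
    for ctype, markers in marker_sets.items():
        present = [m for m in markers if m in adata.var_names]
        if not present:
            warnings.warn(f"no markers of type {ctype!r} in the matrix: unassignable")
            continue
        usable[ctype] = present
    gene_max = cluster_means.max(axis=1).replace(0, np.nan)
    rescaled = cluster_means.div(gene_max, axis=0).fillna(0.0)
    rows = []
    for cid in cluster_ids:
        scores = {t: float(rescaled.loc[m, cid].mean()) for t, m in usable.items()}
        ranked = sorted(scores, key=scores.get, reverse=True)
        if not ranked:
            call = "unassigned"
        elif len(ranked) > 1 and scores[ranked[0]] - scores[ranked[1]] < margin:
            call = "unassigned"
        else:
            call = ranked[0]
        rows.append({"cluster": cid, "assigned_type": call, **{
            f"score_{t}": s for t, s in scores.items()
        }})
    calls = pd.DataFrame(rows)
    type_of = dict(zip(calls["cluster"], calls["assigned_type"]))
    cell_type = clusters.map(type_of)
    composition = (
        pd.crosstab(adata.obs[group_key], cell_type, normalize="index") * 100
    )
    return calls, composition
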