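"""Mutual-information regulon inference and master-regulator analysis.

A regulon is the set of genes whose expression carries significant mutual
information (MI) with a transcription factor's expression. MI is estimated by
equal-frequency binning on ranks (default b = ceil(sqrt(n/5)) bins);
significance comes from a permutation null per TF (empirical p with +1
smoothing, BH-adjusted across that TF's candidate targets), stability from a
cell bootstrap (edges must be re-detected in a minimum fraction of
resamples), and an optional data-processing-inequality (DPI) prune removes
the weakest edge of fully connected triangles. Master-regulator analysis
scores the enrichment of a query gene list in each regulon with a one-sided
Fisher's exact test, BH-adjusted, flagging regulators at adjusted p < 0.01.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import mutual_info_score

from .stats import benjamini_hochberg

__all__ = [
    "default_n_bins",
    "mutual_information",
    "compute_mi_edges",
    "permutation_filter",
    "bootstrap_filter",
    "dpi_filter",
    "regulons_from_edges",
    "master_regulator_analysis",
    "infer_regulons",
]


def default_n_bins(n: int) -> int:
    """Bin count heuristic: about 5 observations per marginal bin."""
    return max(2, int(np.ceil(np.sqrt(n / 5))))


def _equal_freq_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    ranks = sps.rankdata(x, method="average")
    bins = np.floor((ranks - 0.5) / x.size * n_bins).astype(np.int64)
    return np.clip(bins, 0, n_bins - 1)


def mutual_information(x, y, n_bins: Optional[int] = None) -> float:
    """Binned MI in nats between two equal-length expression vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 8:
        raise ValueError("need at least 8 observations for a binned MI estimate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector: MI is 0 by convention")
        return 0.0
    b = n_bins or default_n_bins(x.size)
    return float(mutual_info_score(_equal_freq_bins(x, b), _equal_freq_bins(y, b)))


def _mi_against(bx: np.ndarray, BY: np.ndarray, n_bins: int) -> np.ndarray:
    """MI of one binned vector against each row of a binned matrix (nats)."""
    m, n = BY.shape
    codes = (np.arange(m)[:, None] * n_bins + BY) * n_bins + bx[None, :]
    joint = np.bincount(codes.ravel(), minlength=m * n_bins * n_bins)
    # joint[g, i, j]: bin i of BY row g against bin j of bx
    joint = joint.reshape(m, n_bins, n_bins).astype(float) / n
    p_row = joint.sum(axis=2)  # (m, n_bins) marginal of each BY row
    p_col = joint.sum(axis=1)  # (m, n_bins) marginal of bx (same for all g)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (p_row[:, :, None] * p_col[:, None, :])
        terms = np.where(joint > 0, joint * np.log(ratio), 0.0)
    return terms.sum(axis=(1, 2))


def _binned_matrix(X: np.ndarray, n_bins: int) -> np.ndarray:
    return np.vstack([_equal_freq_bins(row, n_bins) for row in X])


def compute_mi_edges(
    expr: pd.DataFrame, tfs: Sequence[str], n_bins: Optional[int] = None
) -> pd.DataFrame:
    """MI for every TF x candidate-target pair (all genes except the TF)."""
    tfs = [t for t in tfs if t in expr.index]
    if not tfs:
        raise ValueError("none of the supplied TFs are in the expression matrix")
    n = expr.shape[1]
    b = n_bins or default_n_bins(n)
    binned = pd.DataFrame(
        _binned_matrix(expr.to_numpy(float), b), index=expr.index
    )
    rows = []
    for tf in tfs:
        targets = [g for g in expr.index if g != tf]
        mi = _mi_against(
            binned.loc[tf].to_numpy(), binned.loc[targets].to_numpy(), b
        )
        rows.append(pd.DataFrame({"tf": tf, "target": targets, "mi": mi}))
    edges = pd.concat(rows, ignore_index=True)
    edges.attrs["n_bins"] = b
    edges.attrs["estimator"] = "equal-frequency rank binning"
    return edges


def permutation_filter(
    expr: pd.DataFrame,
    edges: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_bins: Optional[int] = None,
) -> pd.DataFrame:
    """Keep edges whose MI beats a per-TF permutation null.

    For each TF, cell labels of the TF vector are permuted ``n_perm`` times
    and null MIs are computed against every candidate target; the empirical
    p = (1 + #{null >= observed}) / (1 + n_perm) never reaches zero. p values
    are BH-adjusted across each TF's targets; edges with adjusted p < alpha
    survive, annotated with perm_p, adj_p and the null (1-alpha) MI quantile
    (``mi_cutoff``, reused by the bootstrap stage).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for stable empirical p values")
    rng = np.random.default_rng(seed)
    n = expr.shape[1]
    b = n_bins or edges.attrs.get("n_bins") or default_n_bins(n)
    binned = pd.DataFrame(
        _binned_matrix(expr.to_numpy(float), b), index=expr.index
    )
    kept = []
    for tf, sub in edges.groupby("tf", sort=False):
        bx = binned.loc[tf].to_numpy()
        BY = binned.loc[sub["target"]].to_numpy()
        null = np.empty((n_perm, len(sub)))
        for k in range(n_perm):
            null[k] = _mi_against(rng.permutation(bx), BY, b)
        obs = sub["mi"].to_numpy()
        p = (1 + (null >= obs[None, :]).sum(axis=0)) / (1 + n_perm)
        cutoff = np.quantile(null, 1 - alpha, axis=0)
        out = sub.copy()
        out["perm_p"] = p
        out["adj_p"] = benjamini_hochberg(p)
        out["mi_cutoff"] = cutoff
        kept.append(out[out["adj_p"] < alpha])
    result = pd.concat(kept, ignore_index=True) if kept else edges.iloc[:0]
    result.attrs.update(edges.attrs)
    result.attrs["n_perm"] = n_perm
    result.attrs["alpha"] = alpha
    return result


def bootstrap_filter(
    expr: pd.DataFrame,
    edges: pd.DataFrame,
    n_boot: int = 100,
    support_min: float = 0.95,
    seed: int = 0,
    n_bins: Optional[int] = None,
) -> pd.DataFrame:
    """Keep edges re-detected in at least ``support_min`` of cell resamples.

    An edge is re-detected on a resample when its MI there reaches the
    permutation-null cutoff recorded by :func:`permutation_filter`.
    ``support_min=0`` is the identity on the edge set.
    """
    if len(edges) == 0 or n_boot <= 0:
        out = edges.copy()
        out["bootstrap_support"] = 1.0
        return out
    rng = np.random.default_rng(seed)
    n = expr.shape[1]
    b = n_bins or edges.attrs.get("n_bins") or default_n_bins(n)
    X = expr.to_numpy(float)
    gene_idx = {g: i for i, g in enumerate(expr.index)}
    hits = np.zeros(len(edges))
    for _ in range(n_boot):
        cols = rng.integers(0, n, size=n)
        Xb = X[:, cols]
        binned = _binned_matrix(Xb, b)
        for tf, sub in edges.groupby("tf", sort=False):
            bx = binned[gene_idx[tf]]
            BY = binned[[gene_idx[g] for g in sub["target"]]]
            mi_b = _mi_against(bx, BY, b)
            hits[sub.index] += mi_b >= sub["mi_cutoff"].to_numpy()
    out = edges.copy()
    out["bootstrap_support"] = hits / n_boot
    out = out[out["bootstrap_support"] >= support_min].reset_index(drop=True)
    out.attrs.update(edges.attrs)
    out.attrs["n_boot"] = n_boot
    out.attrs["support_min"] = support_min
    return out


def dpi_filter(edges: pd.DataFrame, epsilon: float = 0.0) -> pd.DataFrame:
    """Data-processing-inequality prune of fully connected triangles.

    For every triangle (tf1, tf2, target) present in the edge set — which
    requires tf2 to be among tf1's targets — the weakest of the three edges
    is removed when its MI is below min(other two) * (1 - epsilon).
    ``epsilon=1`` removes nothing; the output is always a subset of the input.
    """
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must lie in [0, 1]")
    mi = {(r.tf, r.target): r.mi for r in edges.itertuples()}
    by_tf: dict = {}
    for tf, target in mi:
        by_tf.setdefault(tf, set()).add(target)
    removed = set()

    def _lookup(a: str, b_: str):
        return mi.get((a, b_)) if (a, b_) in mi else mi.get((b_, a))

    tfs = sorted(by_tf)
    for i, tf1 in enumerate(tfs):
        for tf2 in tfs[i + 1:]:
            link = _lookup(tf1, tf2)
            if link is None:
                continue
            link_key = (tf1, tf2) if (tf1, tf2) in mi else (tf2, tf1)
            for target in by_tf[tf1] & by_tf[tf2]:
                if target in (tf1, tf2):
                    continue
                triangle = [
                    (link, link_key),
                    (mi[(tf1, target)], (tf1, target)),
                    (mi[(tf2, target)], (tf2, target)),
                ]
                triangle.sort(key=lambda t: t[0])
                weakest, others = triangle[0], triangle[1:]
                if weakest[0] < min(o[0] for o in others) * (1 - epsilon):
                    removed.add(weakest[1])
    keep = [
        (r.tf, r.target) not in removed for r in edges.itertuples()
    ]
    out = edges[np.asarray(keep)].reset_index(drop=True)
    out.attrs.update(edges.attrs)
    out.attrs["dpi_epsilon"] = epsilon
    return out


def regulons_from_edges(edges: pd.DataFrame) -> dict:
    """Group surviving targets by TF; a TF is never its own target."""
    return {
        tf: sorted(set(sub["target"]) - {tf})
        for tf, sub in edges.groupby("tf", sort=True)
    }


def master_regulator_analysis(
    regulons: dict,
    query_genes: Sequence[str],
    universe: Sequence[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment of a query list in each regulon.

    The 2x2 table counts genes in/out of the regulon crossed with in/out of
    the query, over the supplied gene universe. p values are BH-adjusted
    across regulons; ``is_master`` flags adjusted p < alpha.
    """
    universe = set(universe)
    query = set(query_genes) & universe
    if not query:
        raise ValueError("empty query gene list (after restriction to universe)")
    rows = []
    for tf, targets in sorted(regulons.items()):
        reg = set(targets) & universe
        overlap = len(reg & query)
        table = np.array(
            [
                [overlap, len(reg) - overlap],
                [len(query) - overlap, len(universe) - len(reg) - len(query) + overlap],
            ]
        )
        _, p = sps.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "tf": tf,
                "regulon_size": len(reg),
                "overlap": overlap,
                "query_size": len(query),
                "universe_size": len(universe),
                "fisher_p": float(p),
            }
        )
    result = pd.DataFrame(rows)
    result["adj_p"] = benjamini_hochberg(result["fisher_p"])
    result["is_master"] = result["adj_p"] < alpha
    return result


def infer_regulons(
    expr: pd.DataFrame,
    tfs: Sequence[str],
    n_perm: int = 1000,
    alpha: float = 0.05,
    n_boot: int = 100,
    support_min: float = 0.95,
    dpi_epsilon: Optional[float] = None,
    seed: int = 0,
    n_bins: Optional[int] = None,
) -> tuple:
    """Full network inference: MI -> permutation -> bootstrap -> optional DPI.

    Returns (edges DataFrame, regulon dict). Each stage only removes edges.
    """
    rng = np.random.default_rng(seed)
    perm_seed, boot_seed = rng.integers(0, 2**31 - 1, size=2)
    edges = compute_mi_edges(expr, tfs, n_bins=n_bins)
    edges = permutation_filter(
        expr, edges, n_perm=n_perm, alpha=alpha, seed=int(perm_seed), n_bins=n_bins
    )
    edges = bootstrap_filter(
        expr, edges, n_boot=n_boot, support_min=support_min,
        seed=int(boot_seed), n_bins=n_bins,
    )
    if dpi_epsilon is not None:
        edges = dpi_filter(edges, epsilon=dpi_epsilon)
    return edges, regulons_from_edges(edges)
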