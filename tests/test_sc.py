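import itertools

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import stats as sps

from rgctools import sc
from rgctools.sc import QCThresholds


def _adata(X, **obs):
    X = np.asarray(X)
    return AnnData(
        X=X,
        obs=pd.DataFrame(obs, index=[f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(X.shape[1])]),
    )


class TestQC:
    def test_cell_boundary_at_least_300_genes(self):
        rng = np.random.default_rng(0)
        X = np.zeros((3, 400), dtype=int)
        X[0, :299] = 1  # removed
        X[1, :300] = 1  # kept
        X[2, :] = rng.integers(1, 5, 400)  # kept
        out = sc.qc_filter(_adata(X), QCThresholds(min_cells_per_gene=0))
        assert out.n_obs == 2
        assert out.uns["qc"]["cells_removed"] == 1

    def test_gene_kept_with_exactly_three_cells(self):
        X = np.ones((5, 20), dtype=int)
        X[:, 0] = [1, 1, 1, 0, 0]  # detected in exactly 3 cells -> kept
        X[:, 1] = [1, 1, 0, 0, 0]  # 2 cells -> removed
        out = sc.qc_filter(_adata(X), QCThresholds(min_genes_per_cell=0,
                                                   min_cells_per_gene=3))
        assert out.n_vars == 19

    def test_idempotent(self, small_counts):
        _, adata = small_counts
        once = sc.qc_filter(adata)
        twice = sc.qc_filter(once)
        assert twice.shape == once.shape
        assert np.array_equal(twice.X, once.X)

    def test_planted_failures_counted(self):
        rng = np.random.default_rng(1)
        X = rng.integers(1, 10, size=(50, 400))
        X[:5, 100:] = 0  # five cells with only 100 detected genes
        out = sc.qc_filter(_adata(X))
        assert out.uns["qc"]["cells_removed"] == 5

    def test_empty_result_raises_with_counts(self):
        X = np.ones((4, 10), dtype=int)
        with pytest.raises(ValueError, match="cells_removed"):
            sc.qc_filter(_adata(X), QCThresholds(min_genes_per_cell=100))


class TestLogNormalize:
    def test_single_gene_closed_form(self):
        out = sc.lognormalize(_adata([[10]]))
        assert out.X[0, 0] == pytest.approx(np.log1p(1e4))

    def test_expm1_row_sums_equal_scale(self, small_counts):
        _, adata = small_counts
        out = sc.lognormalize(sc.qc_filter(adata))
        sums = np.expm1(out.X).sum(axis=1)
        assert sums == pytest.approx(np.full(out.n_obs, 1e4), rel=1e-6)

    def test_zero_total_cell_rejected(self):
        X = np.array([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="zero-total"):
            sc.lognormalize(_adata(X))


class TestPCA:
    def test_rank_one_structure_captured_by_pc1(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=(200, 1))
        v = rng.normal(size=(1, 40))
        X = u @ v + 0.01 * rng.normal(size=(200, 40))
        adata = _adata(X)
        out = sc.hvg_scale_pca(adata, n_pcs=5, n_top_genes=40)
        var = out.obsm["X_pca"].var(axis=0)
        assert var[0] / var.sum() > 0.95

    def test_embeddings_deterministic(self, small_counts):
        _, adata = small_counts
        norm = sc.lognormalize(sc.qc_filter(adata))
        a = sc.hvg_scale_pca(norm)
        b = sc.hvg_scale_pca(norm)
        assert np.array_equal(a.obsm["X_pca"], b.obsm["X_pca"])

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="fewer genes"):
            sc.hvg_scale_pca(_adata(np.ones((10, 3))), n_pcs=5)


class TestClustering:
    def _blobs(self, seed=3):
        from sklearn.datasets import make_blobs

        X, y = make_blobs(n_samples=300, centers=3, n_features=10,
                          cluster_std=0.5, random_state=seed)
        adata = _adata(np.zeros((300, 12)), truth=y)
        adata.obsm["X_pca"] = X
        return adata

    def test_separated_blobs_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        adata = sc.cluster_cells(self._blobs(), resolution=0.5, seed=0)
        ari = adjusted_rand_score(adata.obs["truth"], adata.obs["cluster"])
        assert ari > 0.9

    def test_fixed_seed_reproduces_labels(self):
        a = sc.cluster_cells(self._blobs(), seed=1)
        b = sc.cluster_cells(self._blobs(), seed=1)
        assert (a.obs["cluster"] == b.obs["cluster"]).all()

    def test_too_few_cells_rejected(self):
        adata = self._blobs()[:10].copy()
        with pytest.raises(ValueError, match="kNN"):
            sc.cluster_cells(adata, k=20)


class TestWilcoxonDEG:
    def test_identical_groups_yield_nothing(self):
        X = np.tile(np.arange(1.0, 21.0), (8, 1))
        adata = _adata(X, group=["a"] * 4 + ["b"] * 4)
        deg = sc.wilcoxon_deg(adata, "group", "a", "b")
        assert (deg["log2fc"] == 0).all()
        assert not deg["significant"].any()

    def test_small_sample_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=8)
        p_pkg = sc.rank_sum_p(vals[:4], vals[4:])
        # oracle: enumerate all 70 assignments of the pooled ranks
        ranks = sps.rankdata(vals)
        mu = 4 * 9 / 2
        obs = abs(ranks[:4].sum() - mu)
        hits = sum(
            abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9
            for idx in itertools.combinations(range(8), 4)
        )
        assert p_pkg == pytest.approx(hits / 70)
        # tie-free case also matches the exact rank-sum distribution
        assert p_pkg == pytest.approx(
            sps.mannwhitneyu(vals[:4], vals[4:], method="exact").pvalue
        )

    def test_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        X = rng.gamma(2, 1, size=(40, 6))
        adata = _adata(X, group=["a"] * 20 + ["b"] * 20)
        adata2 = _adata(np.log1p(X) ** 2, group=["a"] * 20 + ["b"] * 20)
        p1 = sc.wilcoxon_deg(adata, "group", "a", "b")["p_value"]
        p2 = sc.wilcoxon_deg(adata2, "group", "a", "b")["p_value"]
        assert p1.to_numpy() == pytest.approx(p2.to_numpy())

    def test_asymptotic_p_close_to_scipy(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 35)
        p_pkg = sc.rank_sum_p(a, b)
        p_sp = sps.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert p_pkg == pytest.approx(p_sp, rel=1e-6)

    def test_planted_markers_recovered(self, small_counts):
        _, adata = small_counts
        norm = sc.lognormalize(sc.qc_filter(adata))
        sub = norm[norm.obs["true_type"].isin(["RGC", "EN"])].copy()
        deg = sc.wilcoxon_deg(sub, "true_type", "RGC", "EN")
        planted = set(adata.uns["marker_sets"]["RGC"]) | set(
            adata.uns["marker_sets"]["EN"]
        )
        planted &= set(deg["gene"])
        sig = set(deg.loc[deg["significant"], "gene"])
        assert len(sig & planted) / len(planted) > 0.9
        assert len(sig - planted) / max(len(sig), 1) <= 0.1

    def test_tiny_group_warns_and_uses_exact_p(self):
        X = np.arange(24.0).reshape(12, 2)
        adata = _adata(X, group=["a"] * 2 + ["b"] * 10)
        with pytest.warns(UserWarning, match="exact"):
            deg = sc.wilcoxon_deg(adata, "group", "a", "b")
        assert (deg["p_value"] > 0).all()


class TestAnnotation:
    def _typed_adata(self):
        # three clusters, each expressing one marker set
        markers = {"RGC": ["Hes5", "Pax6"], "IP": ["Eomes", "Hes6"],
                   "EN": ["Neurod6", "Tubb3"]}
        genes = [g for v in markers.values() for g in v]
        X = np.ones((30, 6)) * 0.1
        for i, ctype in enumerate(markers):
            X[i * 10:(i + 1) * 10, 2 * i:2 * i + 2] = 5.0
        adata = AnnData(
            X=X,
            obs=pd.DataFrame(
                {
                    "cluster": np.repeat(["0", "1", "2"], 10),
                    "group": ["CAG", "Hes5"] * 15,
                },
                index=[f"c{i}" for i in range(30)],
            ),
            var=pd.DataFrame(index=genes),
        )
        return adata, markers

    def test_marker_dominated_clusters_assigned(self):
        adata, markers = self._typed_adata()
        calls, composition = sc.annotate_and_compose(adata, markers)
        assert dict(zip(calls["cluster"], calls["assigned_type"])) == {
            "0": "RGC", "1": "IP", "2": "EN"
        }
        assert composition.loc["CAG"].sum() == pytest.approx(100.0)

    def test_scores_within_margin_left_unassigned(self):
        adata, markers = self._typed_adata()
        adata.X = np.ones_like(adata.X)  # every set scores identically
        calls, _ = sc.annotate_and_compose(adata, markers)
        assert (calls["assigned_type"] == "unassigned").all()

    def test_missing_marker_set_warned(self):
        adata, markers = self._typed_adata()
        markers = {**markers, "oRGC": ["NotAGene"]}
        with pytest.warns(UserWarning, match="unassignable"):
            sc.annotate_and_compose(adata, markers)

    def test_composition_recovers_planted_group_design(self, small_counts):
        cfg, adata = small_counts
        norm = sc.lognormalize(sc.qc_filter(adata))
        clusters = norm.obs["true_type"].astype(str)
        norm.obs["cluster"] = clusters
        _, composition = sc.annotate_and_compose(
            norm, {k: v for k, v in adata.uns["marker_sets"].items()}
        )
        for group in ("CAG", "Hes5"):
            planted = cfg.type_proportions[group]
            for ctype in ("RGC", "IP", "EN"):
                assert composition.loc[group, ctype] == pytest.approx(
                    100 * planted[ctype], abs=8.0
                )
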