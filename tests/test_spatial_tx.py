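"""Binning, QC filtering, normalization, clustering and markers."""

import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spatialfuse import spatial_tx as stx
from spatialfuse.reference import ToyReference
from spatialfuse.stereo_reads import SpotExpression


def _spot_expression(counts, xy, pitch=0.5, genes=None, mito=None, section=0):
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[1])]
    spots = pd.DataFrame(xy, columns=["x_index", "y_index"])
    spots["x_um"] = spots["x_index"] * pitch
    spots["y_um"] = spots["y_index"] * pitch
    spots["n_reads"] = counts.sum(axis=1)
    return SpotExpression(
        counts=sp.csr_matrix(counts),
        genes=genes,
        spots=spots,
        mito_gene_mask=np.asarray(mito if mito is not None else [False] * counts.shape[1]),
        microbe_counts=pd.Series(dtype=np.int64),
        pitch_um=pitch,
        section=section,
    )


class TestBinSpots:
    def test_bin_size_one_identity(self):
        m = _spot_expression([[1, 2], [3, 4]], [(0, 0), (1, 1)])
        b = stx.bin_spots(m, 1)
        assert b.n_obs == 2
        assert np.array_equal(np.asarray(b.X.todense()), [[1, 2], [3, 4]])

    def test_bin50_side_is_25um_at_half_micron_pitch(self):
        m = _spot_expression([[1]], [(0, 0)], pitch=0.5)
        b = stx.bin_spots(m, 50)
        assert b.uns["bin_side_um"] == pytest.approx(25.0)
        b20 = stx.bin_spots(m, 20)
        assert b20.uns["bin_side_um"] == pytest.approx(10.0)

    def test_counts_conserved_random(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.3, size=(100, 7))
        xy = [(i % 10, i // 10) for i in range(100)]
        m = _spot_expression(counts, xy)
        for size in (1, 3, 4, 10):
            b = stx.bin_spots(m, size)
            assert np.array_equal(
                np.asarray(b.X.sum(axis=0)).ravel(), counts.sum(axis=0)
            ), f"per-gene totals must survive binning at size {size}"

    def test_bin_index_floor(self):
        m = _spot_expression([[1], [1], [1]], [(0, 0), (49, 0), (50, 0)])
        b = stx.bin_spots(m, 50)
        assert sorted(zip(b.obs["bin_x"], b.obs["bin_y"])) == [(0, 0), (1, 0)]


def _binned(counts, mito_col=None):
    counts = np.asarray(counts, dtype=float)
    var = pd.DataFrame(
        {"is_mito": [i == mito_col for i in range(counts.shape[1])]},
        index=[f"G{i}" for i in range(counts.shape[1])],
    )
    obs = pd.DataFrame(
        {
            "bin_x": np.arange(len(counts)),
            "bin_y": 0,
            "section": 0,
        },
        index=[f"b{i}" for i in range(len(counts))],
    )
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)


class TestQCFilter:
    def test_bin_with_two_genes_removed(self):
        # 5 bins; bin 0 has only 2 detected genes
        counts = np.array(
            [
                [5, 5, 0, 0],
                [1, 1, 1, 1],
                [2, 2, 2, 0],
                [1, 0, 1, 1],
                [3, 1, 1, 1],
            ]
        )
        out = stx.qc_filter(_binned(counts))
        assert "b0" not in out.obs_names

    def test_mito_20pct_kept_25pct_removed(self):
        # gene 3 is mitochondrial
        counts = np.array(
            [
                [4, 2, 2, 2],  # mito 20% exactly -> kept
                [3, 2, 1, 2],  # mito 25% -> removed
                [4, 3, 1, 0],
                [5, 1, 2, 1],
                [2, 2, 2, 1],
            ]
        )
        out = stx.qc_filter(_binned(counts, mito_col=3))
        assert "b0" in out.obs_names and "b1" not in out.obs_names

    def test_hand_enumerated_fixture(self):
        counts = np.array(
            [
                [1, 1, 1, 0],
                [2, 0, 1, 1],
                [1, 1, 0, 1],
                [9, 0, 0, 0],  # 1 gene -> drop
                [1, 1, 1, 1],
            ]
        )
        out = stx.qc_filter(_binned(counts))
        # after dropping b3, gene 0 still in >= 3 bins; all genes kept
        assert list(out.obs_names) == ["b0", "b1", "b2", "b4"]

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(0.8, size=(30, 8))
        once = stx.qc_filter(_binned(counts))
        twice = stx.qc_filter(once)
        assert list(once.obs_names) == list(twice.obs_names)
        assert list(once.var_names) == list(twice.var_names)

    def test_all_removed_raises(self):
        counts = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(stx.EmptyResultError):
            stx.qc_filter(_binned(counts))


class TestPreprocess:
    def test_zero_bin_stays_zero(self):
        counts = np.array([[0, 0, 0], [1, 2, 3], [2, 2, 2], [4, 1, 0]])
        out = stx.preprocess([_binned(counts)])
        assert np.allclose(np.asarray(out.X.todense())[0], 0.0)

    def test_two_identical_sections_symmetric(self):
        counts = np.array([[1, 2, 3], [2, 2, 2], [4, 1, 0]])
        a, b = _binned(counts), _binned(counts)
        b.obs["section"] = 1
        out = stx.preprocess([a, b], merge=True)
        X = np.asarray(out.X.todense())
        assert np.allclose(X[:3], X[3:])

    def test_monotone_within_bin(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(2.0, size=(10, 12))
        out = stx.preprocess([_binned(counts)])
        X = np.asarray(out.X.todense())
        for i in range(10):
            order = np.argsort(counts[i], kind="stable")
            assert np.all(np.diff(X[i][order]) >= -1e-12)


class TestCluster:
    def _two_program_adata(self, n_per=100, seed=0):
        # two symmetric 60-gene programs with 12 planted 4x markers each
        rng = np.random.default_rng(seed)
        rate_a = np.r_[np.full(12, 28.0), np.full(12, 7.0), np.full(36, 7.0)]
        rate_b = np.r_[np.full(12, 7.0), np.full(12, 28.0), np.full(36, 7.0)]
        a = rng.poisson(rate_a, size=(n_per, 60))
        b = rng.poisson(rate_b, size=(n_per, 60))
        adata = _binned(np.vstack([a, b]))
        adata.obs["section"] = 0
        return stx.preprocess([adata])

    def test_two_programs_two_clusters(self):
        from sklearn.metrics import silhouette_score

        adata = self._two_program_adata()
        out = stx.cluster(adata, seed=0)
        labels = out.obs["leiden"].astype(int).to_numpy()
        assert labels.max() + 1 == 2
        assert silhouette_score(out.obsm["X_pca"], labels) > 0.5
        truth = np.array([0] * 100 + [1] * 100)
        assert (pd.crosstab(truth, labels).to_numpy().min(axis=1) == 0).all()

    def test_duplicated_sections_do_not_drive_clusters(self):
        """Clustering a dataset duplicated as two "sections" ignores the
        section label: every bin and its duplicate land in one cluster."""
        from sklearn.metrics import adjusted_rand_score

        adata = self._two_program_adata()
        doubled = ad.concat(
            [adata, adata], label="batch_section", index_unique="-"
        )
        both = stx.cluster(doubled, seed=0).obs["leiden"].astype(int).to_numpy()
        n = adata.n_obs
        assert adjusted_rand_score(both[:n], both[n:]) == 1.0
        assert (both[:n] == both[n:]).all()

    def test_identical_rows_single_cluster(self):
        adata = _binned(np.tile([3, 1, 2], (30, 1)))
        out = stx.cluster(stx.preprocess([adata]), seed=0)
        assert out.obs["leiden"].nunique() == 1

    def test_too_few_bins_raises(self):
        adata = stx.preprocess([_binned(np.eye(4) + 1)])
        with pytest.raises(ValueError, match="n_neighbors"):
            stx.cluster(adata, n_neighbors=15, seed=0)

    def test_deterministic_given_seed(self):
        adata = self._two_program_adata()
        l1 = stx.cluster(adata.copy(), seed=3).obs["leiden"].tolist()
        l2 = stx.cluster(adata.copy(), seed=3).obs["leiden"].tolist()
        assert l1 == l2


def _ranksum_oracle(x, y):
    """From-scratch two-sided rank-sum normal approximation (tie-averaged)."""
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sv = pooled[order]
    i = 0
    while i < len(sv):
        j = i
        while j < len(sv) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)  # average rank of the tie group
        i = j
    n1, n2 = len(x), len(y)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (w - mu) / sigma
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return z, p


class TestRankAndSelect:
    def _adata(self, X, labels, sections=None):
        adata = _binned(X)
        adata.obs["cluster"] = pd.Categorical([str(l) for l in labels])
        adata.obs["section"] = sections if sections is not None else 0
        return adata

    def test_identical_distribution_not_selected(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(5.0, size=(40, 4)).astype(float)
        labels = [0] * 20 + [1] * 20
        mk = stx.rank_and_select(self._adata(X, labels), labels="cluster")
        assert not mk.table["selected"].any()

    def test_planted_marker_selected_and_p_matches_oracle(self):
        rng = np.random.default_rng(1)
        n = 50
        base = rng.poisson(5.0, size=(2 * n * 3, 6)).astype(float)
        labels = np.tile([0] * n + [1] * n, 3)
        sections = np.repeat([0, 1, 2], 2 * n)
        base[labels == 0, 0] = rng.poisson(20.0, (labels == 0).sum())  # 4x marker
        adata = self._adata(base, labels, sections)
        mk = stx.rank_and_select(adata, labels="cluster")
        sel = mk.selected(cluster="0")
        assert list(sel["gene"]) == ["G0"]
        # pooled Wilcoxon p for every (cluster, gene) matches the oracle
        import scanpy as sc  # noqa: F401  (normalized layers not needed here)

        X = base
        for row in mk.table.itertuples():
            j = int(row.gene[1:])
            in_cl = labels == int(row.cluster)
            z, p = _ranksum_oracle(X[in_cl, j], X[~in_cl, j])
            assert row.statistic == pytest.approx(z, abs=1e-10)
            assert row.pval == pytest.approx(p, abs=1e-10)

    def test_low_fold_change_excluded(self):
        """log2FC 0.93 with tiny p is still excluded by the FC gate."""
        rng = np.random.default_rng(2)
        n = 400
        X = np.empty((2 * n, 2))
        X[:n, 0] = rng.normal(100.0, 1.0, n)
        X[n:, 0] = rng.normal(52.4, 1.0, n)  # FC ~ 1.91 -> log2 ~ 0.93
        X[:, 1] = rng.poisson(5.0, 2 * n)
        X = np.log1p(X)  # rank_and_select expects log-normalized values
        labels = [0] * n + [1] * n
        adata = self._adata(np.expm1(X), labels)
        adata.X = sp.csr_matrix(X)
        mk = stx.rank_and_select(adata, labels="cluster")
        g0 = mk.table[(mk.table["cluster"] == "0") & (mk.table["gene"] == "G0")].iloc[0]
        assert g0.pval < 1e-9
        assert 0.8 < g0.log2fc < 1.0
        assert not g0.selected

    def test_single_cluster_raises(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="two clusters"):
            stx.rank_and_select(self._adata(X, [0] * 10), labels="cluster")


class TestPlantedRecovery:
    """End-to-end parameter recovery on the shared phantom run."""

    def test_leiden_recovers_compartments(self, recovery_run):
        from sklearn.metrics import adjusted_rand_score

        phantom, merged = recovery_run
        truth = phantom.compartment_at(
            merged.obs[["x_um", "y_um"]].to_numpy(), with_interface=False
        )
        labels = merged.obs["leiden"].astype(int).to_numpy()
        assert adjusted_rand_score(truth, labels) >= 0.8

    def test_marker_selection_sensitivity_specificity(self, recovery_run):
        phantom, merged = recovery_run
        mk = stx.rank_and_select(merged)
        planted = {
            "tumor": {g for g in phantom.reference.host_genes if g.startswith("TUM")},
            "stroma": {g for g in phantom.reference.host_genes if g.startswith("STR")},
        }
        truth = phantom.compartment_at(
            merged.obs[["x_um", "y_um"]].to_numpy(), with_interface=False
        )
        labels = merged.obs["leiden"].astype(int).to_numpy()
        # map each compartment to its dominant Leiden cluster
        hit = set()
        for comp, genes in planted.items():
            code = phantom.compartment_code(comp)
            counts = pd.Series(labels[truth == code]).value_counts()
            cl = str(counts.idxmax())
            selected = set(mk.selected(cluster=cl)["gene"])
            assert selected == genes, f"{comp}: {selected ^ genes}"
            hit |= selected
        # no spurious selections elsewhere
        assert set(mk.selected()["gene"]) == hit
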