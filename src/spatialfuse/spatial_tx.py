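"""Bin-level expression analysis: binning, QC, clustering, markers.

Spots are aggregated into square bins of ``bin_size`` spots per side
(bin50 at the 0.5 um chip pitch = 25 um x 25 um, the working resolution
for Leiden-voxel integration). Bins are QC-filtered, sections merged and
normalized, clustered with Leiden on a PCA/kNN graph, and per-cluster
marker genes selected by a Wilcoxon rank-sum test at p < 0.01 with
log2 fold change > 1, required in every section of the batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
import scipy.stats

from .stereo_reads import SpotExpression

MIN_GENES_PER_BIN = 3
MIN_BINS_PER_GENE = 3
MAX_MITO_PCT = 20.0
P_THRESHOLD = 0.01
LOG2FC_THRESHOLD = 1.0
_FC_PSEUDOCOUNT = 1e-9


class EmptyResultError(ValueError):
    """All bins (or all genes) were removed by filtering."""


def bin_spots(matrix: SpotExpression, bin_size: int) -> ad.AnnData:
    """Sum spot counts into ``bin_size`` x ``bin_size`` spot bins.

    Bin index = ``floor(spot_index / bin_size)`` per axis; counts are
    conserved. Returns an AnnData with obs ``bin_x``, ``bin_y``,
    ``section``, per-bin read/mito tallies and bin-center coordinates;
    ``uns`` records bin size, pitch and physical bin side (um).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    bx = matrix.spots["x_index"].to_numpy() // bin_size
    by = matrix.spots["y_index"].to_numpy() // bin_size
    keys = pd.DataFrame({"bin_x": bx, "bin_y": by})
    uniq, inverse = np.unique(keys.values, axis=0, return_inverse=True)
    n_bins = len(uniq)
    member = sp.csr_matrix(
        (np.ones(len(bx)), (inverse, np.arange(len(bx)))),
        shape=(n_bins, len(bx)),
    )
    counts = sp.csr_matrix(member @ matrix.counts)

    side_um = bin_size * matrix.pitch_um
    obs = pd.DataFrame(
        {
            "bin_x": uniq[:, 0],
            "bin_y": uniq[:, 1],
            "section": matrix.section,
            "x_um": (uniq[:, 0] + 0.5) * side_um,
            "y_um": (uniq[:, 1] + 0.5) * side_um,
            "n_reads": np.asarray(member @ matrix.spots["n_reads"].to_numpy()).ravel(),
        }
    )
    obs.index = [f"s{matrix.section}_bin_{x}_{y}" for x, y in uniq]
    var = pd.DataFrame(
        {"is_mito": matrix.mito_gene_mask}, index=pd.Index(matrix.genes, name="gene")
    )
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.obs["mito_counts"] = np.asarray(
        counts[:, matrix.mito_gene_mask].sum(axis=1)
    ).ravel() if matrix.mito_gene_mask.any() else 0
    adata.obs["total_counts"] = np.asarray(counts.sum(axis=1)).ravel()
    adata.uns.update(
        bin_size=bin_size, pitch_um=matrix.pitch_um, bin_side_um=side_um
    )
    return adata


def qc_filter(binned: ad.AnnData) -> ad.AnnData:
    """Remove low-quality bins and rarely detected genes.

    Bins with fewer than 3 detected genes or mitochondrial percentage
    strictly above 20% are excluded; genes detected in fewer than 3 bins
    are dropped. The two filters are iterated to a fixed point so the
    operation is idempotent.
    """
    adata = binned.copy()
    while True:
        X = sp.csr_matrix(adata.X)
        mito_mask = adata.var["is_mito"].to_numpy()
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
        total = np.asarray(X.sum(axis=1)).ravel()
        mito = (
            np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
            if mito_mask.any()
            else np.zeros(adata.n_obs)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_pct = np.where(total > 0, 100.0 * mito / np.maximum(total, 1), 0.0)
        keep_bins = (n_genes >= MIN_GENES_PER_BIN) & (mito_pct <= MAX_MITO_PCT)
        n_bins_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
        keep_genes = n_bins_per_gene >= MIN_BINS_PER_GENE
        if keep_bins.all() and keep_genes.all():
            break
        adata = adata[keep_bins, :][:, keep_genes].copy()
        if adata.n_obs == 0 or adata.n_vars == 0:
            raise EmptyResultError("QC filtering removed all bins or genes")
    adata.obs["n_genes"] = np.asarray((sp.csr_matrix(adata.X) > 0).sum(axis=1)).ravel()
    return adata


def preprocess(
    binned: Sequence[ad.AnnData],
    merge: bool = True,
    target_sum: float | None = None,
    batch_correct: Callable[[ad.AnnData], ad.AnnData] | None = None,
) -> ad.AnnData:
    """Merge sections, normalize library sizes, and log1p-transform.

    Per-bin counts are scaled to ``target_sum`` (default: the median
    per-bin total across the merged data) and log1p is applied
    elementwise. ``batch_correct`` is a pluggable hook applied after the
    transform (latent-space batch integration is out of scope; default is
    a no-op).
    """
    if len(binned) == 0:
        raise ValueError("need at least one section")
    if not merge and len(binned) > 1:
        # normalize each section on its own scale, then concatenate
        parts = [preprocess([b], target_sum=target_sum) for b in binned]
        merged = ad.concat(parts, join="inner", label="batch_section", index_unique="-")
        if batch_correct is not None:
            merged = batch_correct(merged)
        return merged
    if len(binned) > 1:
        merged = ad.concat(
            list(binned), join="inner", label="batch_section", index_unique="-"
        )
    else:
        merged = binned[0].copy()
    for key in ("bin_size", "pitch_um", "bin_side_um"):
        if key in binned[0].uns:
            merged.uns[key] = binned[0].uns[key]
    merged.layers["counts"] = sp.csr_matrix(merged.X).copy()
    sc.pp.normalize_total(merged, target_sum=target_sum)
    sc.pp.log1p(merged)
    if batch_correct is not None:
        merged = batch_correct(merged)
    return merged


def cluster(
    matrix: ad.AnnData,
    n_pcs: int = 50,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    key_added: str = "leiden",
) -> ad.AnnData:
    """PCA -> kNN graph -> Leiden community labels (seeded).

    Every bin receives a label (stored as ``obs[key_added]``, integer
    categories). Deterministic given ``seed``.
    """
    if matrix.n_obs == 0:
        raise ValueError("empty matrix")
    if matrix.n_obs <= n_neighbors:
        raise ValueError(
            f"{matrix.n_obs} bins but n_neighbors={n_neighbors}; need more bins"
        )
    adata = matrix
    if np.allclose(
        np.asarray(sp.csr_matrix(adata.X).todense()).std(axis=0), 0.0
    ):
        # degenerate: identical rows; single community
        adata.obs[key_added] = pd.Categorical(["0"] * adata.n_obs)
        return adata
    n_comps = int(min(n_pcs, adata.n_vars - 1, adata.n_obs - 1))
    sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, random_state=seed)
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=seed,
        key_added=key_added,
        flavor="leidenalg",
    )
    return adata


# ---------------------------------------------------------------------------
# marker selection


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (normal approximation) via scipy."""
    stat, p = scipy.stats.ranksums(x, y)
    return float(stat), float(p)


def _log2fc(in_vals: np.ndarray, out_vals: np.ndarray) -> float:
    """log2 fold change on normalized data via mean expm1, pseudo-counted."""
    a = np.expm1(in_vals).mean() + _FC_PSEUDOCOUNT
    b = np.expm1(out_vals).mean() + _FC_PSEUDOCOUNT
    return float(np.log2(a / b))


@dataclass
class MarkerTable:
    """Per-(cluster, gene) Wilcoxon statistics and selection flags."""

    table: pd.DataFrame

    def selected(self, cluster: str | int | None = None) -> pd.DataFrame:
        sel = self.table[self.table["selected"]]
        if cluster is not None:
            sel = sel[sel["cluster"] == str(cluster)]
        return sel

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rank_and_select(
    matrix: ad.AnnData,
    labels: str | Sequence = "leiden",
    section_key: str = "section",
    p_threshold: float = P_THRESHOLD,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
) -> MarkerTable:
    """Per-cluster marker genes, cluster-vs-rest, shared across sections.

    For every cluster and gene a two-sided Wilcoxon rank-sum test compares
    the cluster's bins against all other bins, per section. A gene is
    selected for a cluster iff p < 0.01 and log2FC > 1 in *every* section.
    Reported statistics are from the pooled (all-section) comparison; raw
    p-values are used for selection and a BH-adjusted column is included
    for transparency.
    """
    lab = (
        matrix.obs[labels].astype(str).to_numpy()
        if isinstance(labels, str)
        else np.asarray(labels, dtype=str)
    )
    clusters = sorted(set(lab))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters to rank markers")
    sections = (
        matrix.obs[section_key].to_numpy()
        if section_key in matrix.obs
        else np.zeros(matrix.n_obs, dtype=int)
    )
    X = np.asarray(sp.csr_matrix(matrix.X).todense())
    genes = list(matrix.var_names)
    uniq_sections = sorted(pd.unique(sections))

    rows = []
    for cl in clusters:
        in_cl = lab == cl
        if in_cl.sum() < 2:
            import warnings

            warnings.warn(f"cluster {cl} has fewer than 2 bins; skipped")
            continue
        for j, gene in enumerate(genes):
            stat, p = rank_sum_test(X[in_cl, j], X[~in_cl, j])
            lfc = _log2fc(X[in_cl, j], X[~in_cl, j])
            ok_sections = []
            for sec in uniq_sections:
                s = sections == sec
                if in_cl[s].sum() < 1 or (~in_cl & s).sum() < 1:
                    continue
                _, p_s = rank_sum_test(X[in_cl & s, j], X[~in_cl & s, j])
                lfc_s = _log2fc(X[in_cl & s, j], X[~in_cl & s, j])
                if p_s < p_threshold and lfc_s > log2fc_threshold:
                    ok_sections.append(sec)
            selected = len(ok_sections) == len(uniq_sections)
            rows.append(
                (cl, gene, stat, p, lfc, selected,
                 ",".join(str(s) for s in ok_sections))
            )
    table = pd.DataFrame(
        rows,
        columns=["cluster", "gene", "statistic", "pval", "log2fc", "selected", "sections"],
    )
    # BH adjustment within each cluster, for transparency only
    def _bh(p: np.ndarray) -> np.ndarray:
        n = len(p)
        order = np.argsort(p)
        ranked = p[order] * n / (np.arange(n) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(ranked, 1.0)
        return out

    table["pval_adj"] = (
        table.groupby("cluster")["pval"].transform(lambda s: _bh(s.to_numpy()))
    )
    return MarkerTable(table)
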