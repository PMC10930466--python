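"""Leiden-voxel indexing, landmark registration and per-voxel aggregation.

The common coordinate frame is the transcriptomics chip's micron grid.
Each labeled bin50 square becomes a "Leiden voxel": a globally unique
16-bit index stored in the image channel of its Leiden cluster. Other
modalities are registered into the frame with landmark-fitted affine
transforms (nearest-neighbour resampling for label rasters), and gene
expression, windowed MSI intensity and phenotyped cell counts are
aggregated per voxel into a :class:`VoxelTable`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .msi_tools import IonImage
from .transform import AffineTransform, DegenerateTransformError

MAX_VOXELS = 65535  # 16-bit index; 0 is reserved for background


class CapacityError(ValueError):
    """More voxels than a 16-bit index can enumerate (> 65535)."""


@dataclass
class LeidenVoxelImage:
    """Multi-channel voxel-index raster at bin resolution.

    ``channels`` has shape ``(n_clusters, ny, nx)`` dtype uint16; channel
    c holds, at every bin of Leiden cluster c, that voxel's globally
    unique index (0 elsewhere). ``index_map`` maps voxel index ->
    ``(bin_x, bin_y, cluster, section)``.
    """

    channels: np.ndarray
    index_map: pd.DataFrame
    bin_size: int
    pitch_um: float
    section: int = 0

    @property
    def voxel_side_um(self) -> float:
        return self.bin_size * self.pitch_um

    @property
    def n_voxels(self) -> int:
        return len(self.index_map)

    def flat(self) -> np.ndarray:
        """Single-plane index raster (channels collapsed)."""
        return self.channels.max(axis=0)

    def cluster_raster(self) -> np.ndarray:
        """Per-bin cluster labels (-1 = background)."""
        out = np.full(self.channels.shape[1:], -1, dtype=int)
        for c in range(self.channels.shape[0]):
            out[self.channels[c] > 0] = c
        return out

    def validate(self) -> None:
        """Assert index uniqueness and channel-cluster consistency."""
        flatten = self.channels.reshape(self.channels.shape[0], -1)
        nonzero = flatten[flatten > 0]
        if len(np.unique(nonzero)) != len(nonzero):
            raise ValueError("voxel indices are not unique")
        if (self.channels > 0).sum(axis=0).max(initial=0) > 1:
            raise ValueError("a voxel appears in more than one channel")
        for row in self.index_map.itertuples():
            if self.channels[row.cluster, row.bin_y, row.bin_x] != row.Index:
                raise ValueError(f"index map inconsistent at voxel {row.Index}")

    def save(self, tiff_path: str | Path, csv_path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(
            str(tiff_path), self.channels, photometric="minisblack",
            metadata={"axes": "CYX"},
        )
        self.index_map.rename_axis("voxel").to_csv(csv_path)


def build_voxel_index(
    cluster_labels: np.ndarray,
    bin_size: int = 50,
    pitch_um: float = 0.5,
    section: int = 0,
) -> LeidenVoxelImage:
    """Enumerate labeled bins into a unique-index multi-channel image.

    ``cluster_labels`` is a 2D array over the bin grid: cluster id per
    bin, negative for background. Indices are consecutive from 1 in
    row-major bin order; more than 65535 voxels raises
    :class:`CapacityError` (the 16-bit indexing limit).
    """
    lab = np.asarray(cluster_labels)
    if lab.ndim != 2:
        raise ValueError("cluster_labels must be 2D (bin grid)")
    labeled = lab >= 0
    n_vox = int(labeled.sum())
    if n_vox == 0:
        raise ValueError("no labeled bins; empty voxel image")
    if n_vox > MAX_VOXELS:
        raise CapacityError(
            f"{n_vox} voxels exceed the 16-bit index capacity of {MAX_VOXELS}"
        )
    n_clusters = int(lab[labeled].max()) + 1
    ny, nx = lab.shape
    channels = np.zeros((n_clusters, ny, nx), dtype=np.uint16)
    ys, xs = np.nonzero(labeled)  # row-major order
    indices = np.arange(1, n_vox + 1, dtype=np.uint16)
    clusters = lab[ys, xs]
    channels[clusters, ys, xs] = indices
    index_map = pd.DataFrame(
        {"bin_x": xs, "bin_y": ys, "cluster": clusters, "section": section},
        index=pd.Index(indices, name="voxel"),
    )
    return LeidenVoxelImage(
        channels=channels,
        index_map=index_map,
        bin_size=bin_size,
        pitch_um=pitch_um,
        section=section,
    )


def labels_from_adata(adata, key: str = "leiden", section=None) -> np.ndarray:
    """Arrange per-bin cluster labels from an AnnData into a bin grid."""
    obs = adata.obs
    if section is not None:
        obs = obs[obs["section"] == section]
    bx = obs["bin_x"].to_numpy(dtype=int)
    by = obs["bin_y"].to_numpy(dtype=int)
    lab = obs[key].astype(int).to_numpy()
    grid = np.full((by.max() + 1, bx.max() + 1), -1, dtype=int)
    grid[by, bx] = lab
    return grid


# ---------------------------------------------------------------------------
# registration


def fit_affine(
    src_points: np.ndarray, dst_points: np.ndarray
) -> tuple[AffineTransform, float]:
    """Least-squares affine from >= 3 landmark pairs; returns RMS residual.

    ``src_points`` are modality coordinates, ``dst_points`` the matching
    reference-frame coordinates. Collinear landmarks raise
    :class:`~spatialfuse.transform.DegenerateTransformError`.
    """
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("landmarks must be matching (n, 2) arrays")
    if len(src) < 3:
        raise ValueError("need at least 3 landmark pairs")
    A = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(A, tol=1e-9 * max(1.0, np.abs(A).max())) < 3:
        raise DegenerateTransformError("landmarks are collinear")
    coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
    transform = AffineTransform(coef.T)
    resid = transform.apply(src) - dst
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return transform, rms


def landmarks_from_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (
        df[["src_x", "src_y"]].to_numpy(float),
        df[["dst_x", "dst_y"]].to_numpy(float),
    )


def save_transform(transform: AffineTransform, path: str | Path,
                   source: str = "", target: str = "reference") -> None:
    with open(path, "w") as fh:
        json.dump(
            {"matrix": transform.matrix.tolist(), "source": source, "target": target},
            fh,
            indent=1,
        )


def load_transform(path: str | Path) -> AffineTransform:
    with open(path) as fh:
        return AffineTransform.from_json_dict(json.load(fh))


def warp_labels(
    image: np.ndarray,
    transform: AffineTransform,
    output_shape: tuple[int, int] | None = None,
    mode: str = "nearest",
    background=0,
) -> np.ndarray:
    """Resample an image under ``transform`` by inverse mapping.

    ``transform`` maps source pixel coordinates to output pixel
    coordinates. ``mode="nearest"`` (required for label/index rasters)
    never creates label values absent from the input; ``mode="linear"``
    is allowed for intensity rasters only.
    """
    if mode not in ("nearest", "linear"):
        raise ValueError("mode must be 'nearest' or 'linear'")
    image = np.asarray(image)
    shape = output_shape or image.shape
    inv = transform.inverse()
    jj, ii = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    out_px = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    src = inv.apply(out_px)
    coords = np.vstack([src[:, 1], src[:, 0]])  # (row, col) ordering
    order = 0 if mode == "nearest" else 1
    warped = ndi.map_coordinates(
        image.astype(float), coords, order=order, mode="constant", cval=background
    )
    out = warped.reshape(shape)
    if mode == "nearest":
        out = out.astype(image.dtype)
    return out


# ---------------------------------------------------------------------------
# aggregation


def aggregate_per_voxel(
    voxel_img: LeidenVoxelImage,
    gene_matrix=None,
    ion_images: Sequence[tuple[str, IonImage, AffineTransform]] = (),
    cell_table: pd.DataFrame | None = None,
    cell_transform: AffineTransform | None = None,
    msi_statistic: str = "mean",
    compartment_mask=None,
    compartment_transform: AffineTransform | None = None,
) -> pd.DataFrame:
    """Join per-voxel records across modalities into a voxel table.

    * genes: ``gene_matrix`` (AnnData with ``bin_x``/``bin_y`` obs at the
      voxel bin size) joins by bin coordinates — inherent alignment;
    * MSI: each ion image pixel center is warped into the reference frame
      and assigned to the voxel whose half-open square it falls in; the
      per-voxel statistic (mean by default, or median/sum) is reported,
      NaN for voxels covered by no pixel;
    * cells: warped centroids counted per voxel and phenotype;
    * compartments: overlap fraction of each voxel with each compartment.
    """
    if msi_statistic not in ("mean", "median", "sum"):
        raise ValueError("msi_statistic must be mean, median or sum")
    side = voxel_img.voxel_side_um
    idx_raster = voxel_img.flat()
    ny, nx = idx_raster.shape
    table = voxel_img.index_map.copy()

    def voxel_of(points_um: np.ndarray) -> np.ndarray:
        """Voxel index per reference-um point (0 = outside/background)."""
        pts = np.atleast_2d(points_um)
        bx = np.floor(pts[:, 0] / side).astype(int)
        by = np.floor(pts[:, 1] / side).astype(int)
        ok = (bx >= 0) & (bx < nx) & (by >= 0) & (by < ny)
        out = np.zeros(len(pts), dtype=int)
        out[ok] = idx_raster[by[ok], bx[ok]]
        return out

    if gene_matrix is not None:
        obs = gene_matrix.obs
        sel = obs["section"] == voxel_img.section if "section" in obs else slice(None)
        sub = gene_matrix[sel]
        key = pd.MultiIndex.from_arrays(
            [sub.obs["bin_x"].astype(int), sub.obs["bin_y"].astype(int)]
        )
        X = np.asarray(
            sub.X.todense() if hasattr(sub.X, "todense") else sub.X
        )
        expr = pd.DataFrame(X, columns=[f"gene_{g}" for g in sub.var_names])
        expr.index = key
        vox_key = pd.MultiIndex.from_arrays([table["bin_x"], table["bin_y"]])
        joined = expr.reindex(vox_key)
        joined.index = table.index
        table = pd.concat([table, joined], axis=1)

    for name, ion, transform in ion_images:
        img = ion.image
        iy, ix = np.nonzero(~np.isnan(img))
        centers_px = np.column_stack([ix + 0.5, iy + 0.5])
        ref_um = transform.apply(centers_px)
        vox = voxel_of(ref_um)
        vals = img[iy, ix]
        ser = pd.Series(vals[vox > 0], index=vox[vox > 0])
        agg = getattr(ser.groupby(level=0), msi_statistic)()
        table[f"mz_{name}"] = agg.reindex(table.index)

    if cell_table is not None:
        cells = cell_table.cells if hasattr(cell_table, "cells") else cell_table
        pts = cells[["x_um", "y_um"]].to_numpy(float)
        if cell_transform is not None:
            pts = cell_transform.apply(pts)
        vox = voxel_of(pts)
        phenos = sorted(cells["phenotype"].unique()) if len(cells) else []
        for ph in phenos:
            sel = (cells["phenotype"] == ph).to_numpy() & (vox > 0)
            counts = pd.Series(vox[sel]).value_counts()
            table[f"cells_{ph}"] = (
                counts.reindex(table.index).fillna(0).astype(int)
            )
        if not phenos:
            pass

    if compartment_mask is not None:
        # overlap fraction via warped compartment raster sampled on a
        # fine grid inside each voxel
        sub = 5  # 5x5 samples per voxel
        names = compartment_mask.names
        offs = (np.arange(sub) + 0.5) / sub * side
        gx, gy = np.meshgrid(offs, offs)
        base = np.column_stack(
            [table["bin_x"].to_numpy() * side, table["bin_y"].to_numpy() * side]
        )
        pts = (base[:, None, :] + np.column_stack([gx.ravel(), gy.ravel()])[None, :, :]).reshape(-1, 2)
        if compartment_transform is not None:
            pts_src = compartment_transform.inverse().apply(pts)
        else:
            pts_src = pts
        px = np.floor(pts_src / compartment_mask.pitch_um).astype(int)
        h, w = compartment_mask.labels.shape
        ok = (px[:, 0] >= 0) & (px[:, 0] < w) & (px[:, 1] >= 0) & (px[:, 1] < h)
        codes = np.zeros(len(px), dtype=int)
        codes[ok] = compartment_mask.labels[px[ok, 1], px[ok, 0]]
        codes = codes.reshape(len(table), sub * sub)
        for ci, cname in enumerate(names):
            if cname == "background":
                continue
            table[f"frac_{cname}"] = (codes == ci).mean(axis=1)
    return table


def cluster_stats(
    voxel_table: pd.DataFrame, quantity: str
) -> pd.DataFrame:
    """Per-cluster summary (mean, variance, quartiles, n) of one column.

    Missing values are excluded; ``n`` reports the voxels actually
    summarized per cluster.
    """
    if quantity not in voxel_table.columns:
        raise KeyError(f"unknown quantity {quantity!r}")
    grp = voxel_table.groupby("cluster")[quantity]
    out = grp.agg(
        n="count",
        mean="mean",
        var="var",
        q25=lambda s: s.quantile(0.25),
        median="median",
        q75=lambda s: s.quantile(0.75),
    )
    return out
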