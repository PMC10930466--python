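"""Serial-section 3D assembly and cross-section proximity.

Registered per-section rasters are stacked along Z and resampled to an
isotropic voxel grid (default 0.23 um, the seqIF XY pixel size): XY is
rescaled to the voxel size and each output Z slice is filled from the
nearest section (nearest-neighbour in Z, consistent with label
semantics). Cross-section cell proximities use Euclidean distance with
dZ given by section Z centers — features one study plane apart are often
closer in Z (~10-20 um) than typical XY neighbour distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .transform import AffineTransform


@dataclass
class SectionStack:
    """Ordered sections with Z geometry and per-section XY transforms."""

    section_ids: list[int]
    z_centers_um: np.ndarray
    thickness_um: float = 5.0
    transforms: dict[int, AffineTransform] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_centers_um = np.asarray(self.z_centers_um, dtype=float)
        if len(self.section_ids) != len(self.z_centers_um):
            raise ValueError("section ids / z centers length mismatch")
        if np.any(np.diff(self.z_centers_um) <= 0):
            raise ValueError("Z centers must be strictly increasing")

    @classmethod
    def from_spacing(
        cls, n_sections: int, spacing_um: float = 10.0, thickness_um: float = 5.0
    ) -> "SectionStack":
        z0 = thickness_um / 2.0
        return cls(
            section_ids=list(range(n_sections)),
            z_centers_um=z0 + spacing_um * np.arange(n_sections),
            thickness_um=thickness_um,
        )

    @property
    def depth_um(self) -> float:
        """Top of first section to bottom of last (thickness-inclusive)."""
        return float(
            (self.z_centers_um[-1] + self.thickness_um / 2.0)
            - (self.z_centers_um[0] - self.thickness_um / 2.0)
        )

    def z_of(self, section_id: int) -> float:
        try:
            return float(self.z_centers_um[self.section_ids.index(section_id)])
        except ValueError:
            raise KeyError(f"unknown section id {section_id}") from None


def assemble_resample(
    stack: SectionStack,
    images: Sequence[np.ndarray],
    pitch_um: float,
    voxel_um: float = 0.23,
    depth_um: float | None = None,
    mode: str = "nearest",
) -> np.ndarray:
    """Stack per-section rasters into an isotropic 3D volume.

    XY is resampled from ``pitch_um`` to ``voxel_um`` preserving the
    aspect ratio; the Z axis spans ``depth_um`` (default: the stack's
    thickness-inclusive depth) with ``floor(depth / voxel)`` slices, each
    filled from the nearest section in Z. ``mode`` is ``nearest`` for
    label rasters, ``linear`` to interpolate intensities between
    sections.
    """
    if voxel_um <= 0:
        raise ValueError("voxel size must be positive")
    if len(images) != len(stack.section_ids):
        raise ValueError("one image per section required")
    if len(images) < 2:
        raise ValueError("need at least 2 sections")
    if mode not in ("nearest", "linear"):
        raise ValueError("mode must be 'nearest' or 'linear'")

    h, w = images[0].shape[:2]
    out_h = int(round(h * pitch_um / voxel_um))
    out_w = int(round(w * pitch_um / voxel_um))
    from scipy.ndimage import zoom

    planes = []
    for img in images:
        if img.shape[:2] != (h, w):
            raise ValueError("all section images must share a shape")
        factors = (out_h / h, out_w / w)
        order = 0 if mode == "nearest" else 1
        planes.append(zoom(np.asarray(img, dtype=np.float32), factors, order=order))
    planes = np.stack(planes)

    depth = stack.depth_um if depth_um is None else float(depth_um)
    n_slices = int(np.floor(depth / voxel_um))
    z0 = stack.z_centers_um[0] - stack.thickness_um / 2.0
    zs = z0 + (np.arange(n_slices) + 0.5) * voxel_um
    if mode == "nearest":
        nearest = np.argmin(
            np.abs(zs[:, None] - stack.z_centers_um[None, :]), axis=1
        )
        volume = planes[nearest]
    else:
        volume = np.empty((n_slices, out_h, out_w), dtype=np.float32)
        zc = stack.z_centers_um
        for k, z in enumerate(zs):
            i = np.clip(np.searchsorted(zc, z) - 1, 0, len(zc) - 2)
            t = np.clip((z - zc[i]) / (zc[i + 1] - zc[i]), 0.0, 1.0)
            volume[k] = (1 - t) * planes[i] + t * planes[i + 1]
    return volume


def save_volume(volume: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), volume.astype(np.float32), metadata={"axes": "ZYX"})


def z_proximity(
    cell_tables: dict[int, pd.DataFrame],
    stack: SectionStack,
    max_distance_um: float = 20.0,
    phenotype: str | None = None,
) -> pd.DataFrame:
    """All cross/within-section cell pairs within a 3D distance threshold.

    Cells take Z from their section's center; distance is Euclidean in
    (x, y, z) um. Returns one row per unordered pair under
    ``max_distance_um`` with both cell ids, sections, and the distance.
    """
    pts, meta = [], []
    for sec, table in cell_tables.items():
        cells = table.cells if hasattr(table, "cells") else table
        z = stack.z_of(sec)  # raises KeyError for unknown sections
        sel = cells
        if phenotype is not None:
            sel = cells[cells["phenotype"] == phenotype]
        for row in sel.itertuples():
            pts.append((row.x_um, row.y_um, z))
            meta.append((sec, row.cell_id))
    if not pts:
        return pd.DataFrame(
            columns=["section_a", "cell_a", "section_b", "cell_b", "distance_um"]
        )
    pts = np.asarray(pts)
    tree = cKDTree(pts)
    pairs = sorted(tree.query_pairs(max_distance_um))
    rows = [
        (
            meta[i][0], meta[i][1], meta[j][0], meta[j][1],
            float(np.linalg.norm(pts[i] - pts[j])),
        )
        for i, j in pairs
    ]
    return pd.DataFrame(
        rows, columns=["section_a", "cell_a", "section_b", "cell_b", "distance_um"]
    )


def pairwise_distance(
    xy_a: tuple[float, float], section_a: int,
    xy_b: tuple[float, float], section_b: int,
    stack: SectionStack,
) -> float:
    """3D distance between two cells given their sections."""
    dz = stack.z_of(section_a) - stack.z_of(section_b)
    dx = xy_a[0] - xy_b[0]
    dy = xy_a[1] - xy_b[1]
    return float(np.sqrt(dx * dx + dy * dy + dz * dz))
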