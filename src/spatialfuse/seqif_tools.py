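"""Sequential immunofluorescence analysis.

Tissue segmentation assigns compartments from marker rule channels
(e.g. Keratin8/18 -> tumor, COL1A1 -> stroma), then erodes each
compartment by 50 um; the union of eroded-away tissue is the
tumor-stroma *interface* band (~100 um across a straight boundary).
Cell segmentation is a deterministic classical pipeline on the DAPI
channel (smooth, threshold, watershed); phenotyping uses the mean of the
top 20% of pixel intensities per cell per marker, clustered with k-means
and named by the dominant marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation

DEFAULT_EROSION_UM = 50.0
TOP_FRACTION = 0.2
MIN_PIXELS_FOR_QUANTILE = 5

INTERFACE = "interface"
BACKGROUND_LABEL = 0


@dataclass
class CompartmentMask:
    """Mutually exclusive compartment label raster.

    ``labels`` holds integer codes indexing ``names`` (code 0 =
    background); ``pitch_um`` converts pixels to microns.
    """

    labels: np.ndarray
    names: list[str]  # names[0] == "background"
    pitch_um: float

    def code(self, name: str) -> int:
        return self.names.index(name)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.code(name)

    def area_um2(self, name: str) -> float:
        return float(self.mask(name).sum()) * self.pitch_um**2

    def compartment_of(self, x_um: float, y_um: float) -> str:
        ix, iy = int(x_um / self.pitch_um), int(y_um / self.pitch_um)
        h, w = self.labels.shape
        if not (0 <= ix < w and 0 <= iy < h):
            return "background"
        return self.names[self.labels[iy, ix]]


def segment_tissue(
    channels: dict[str, np.ndarray],
    rules: dict[str, str],
    erosion_um: float = DEFAULT_EROSION_UM,
    pitch_um: float | None = None,
    thresholds: dict[str, float] | None = None,
    closing_um: float = 0.0,
) -> CompartmentMask:
    """Segment tissue compartments and derive the interface band.

    Each rule channel (marker -> compartment) is thresholded (Otsu unless
    an explicit threshold is given); tissue pixels are assigned to the
    compartment whose rule channel responds most strongly, optionally
    morphologically closed. The named compartments are then each eroded
    by a disk of radius ``erosion_um`` and the tissue pixels removed by
    either erosion become the ``interface`` compartment.
    """
    if pitch_um is None:
        raise ValueError("pixel pitch (um) is required")
    missing = [m for m in rules if m not in channels]
    if missing:
        raise ValueError(f"missing rule channels: {missing}")
    markers = list(rules)
    compartments = list(dict.fromkeys(rules.values()))
    shape = channels[markers[0]].shape

    response = np.zeros((len(markers),) + shape)
    above = np.zeros((len(markers),) + shape, dtype=bool)
    for i, m in enumerate(markers):
        img = np.asarray(channels[m], dtype=float)
        thr = (
            thresholds[m]
            if thresholds and m in thresholds
            else (filters.threshold_otsu(img) if img.min() < img.max() else np.inf)
        )
        above[i] = img > thr
        response[i] = img

    tissue = above.any(axis=0)
    best = np.argmax(np.where(above, response, -np.inf), axis=0)
    labels = np.zeros(shape, dtype=np.int16)
    names = ["background"] + compartments + [INTERFACE]
    for i, m in enumerate(markers):
        code = names.index(rules[m])
        labels[tissue & (best == i)] = code

    if closing_um > 0:
        selem = morphology.disk(int(round(closing_um / pitch_um)))
        for comp in compartments:
            code = names.index(comp)
            closed = morphology.binary_closing(labels == code, selem)
            labels[closed & (labels == 0)] = code

    # erode each compartment by `erosion_um` at its boundary with the
    # *other* compartments; the union of stripped pixels is the interface.
    # Implemented with Euclidean distance transforms, which is identical
    # to disk erosion at a shared boundary but ignores image borders and
    # tissue holes (a lone compartment yields an empty interface).
    radius_px = erosion_um / pitch_um
    interface = np.zeros(shape, dtype=bool)
    for comp in compartments:
        code = names.index(comp)
        m = labels == code
        others = tissue & (labels != code) & (labels != 0)
        if not m.any() or not others.any():
            continue
        dist_to_other = ndi.distance_transform_edt(~others)
        stripped = m & (dist_to_other <= radius_px)
        labels[stripped] = names.index(INTERFACE)
        interface |= stripped
    return CompartmentMask(labels=labels, names=names, pitch_um=float(pitch_um))


@dataclass
class CellTable:
    """Segmented cells with centroid, area, features and labels."""

    cells: pd.DataFrame
    pitch_um: float

    def __len__(self) -> int:
        return len(self.cells)

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def segment_cells(
    dapi: np.ndarray,
    pitch_um: float,
    min_area_um2: float = 20.0,
    max_area_um2: float = 1000.0,
    sigma_um: float = 1.0,
    min_distance_um: float = 4.0,
    cell_dilation_um: float = 2.0,
) -> np.ndarray:
    """Segment nuclei from the DAPI channel; return a cell label image.

    Deterministic classical pipeline: Gaussian smooth, Otsu threshold,
    distance-transform watershed to split touching nuclei, area filter,
    then each nucleus is dilated by ``cell_dilation_um`` (clipped at
    neighbouring cells) to approximate the cell body. A blank image
    yields zero cells.
    """
    img = np.asarray(dapi, dtype=float)
    if img.max() <= img.min():
        return np.zeros(img.shape, dtype=np.int32)
    smoothed = filters.gaussian(img, sigma=sigma_um / pitch_um)
    thr = filters.threshold_otsu(smoothed)
    fg = smoothed > thr
    if not fg.any():
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        dist,
        min_distance=max(1, int(round(min_distance_um / pitch_um))),
        labels=fg,
        exclude_border=False,
    )
    seeds = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    nuclei = segmentation.watershed(-dist, seeds, mask=fg)

    # area filter
    areas = np.bincount(nuclei.ravel())
    px_area = pitch_um**2
    bad = np.nonzero(
        (areas * px_area < min_area_um2) | (areas * px_area > max_area_um2)
    )[0]
    for lb in bad:
        if lb:
            nuclei[nuclei == lb] = 0
    nuclei, _, _ = segmentation.relabel_sequential(nuclei)

    if cell_dilation_um > 0 and nuclei.max() > 0:
        # expand labels; expansion stops where cells meet
        cells = segmentation.expand_labels(
            nuclei, distance=cell_dilation_um / pitch_um
        )
    else:
        cells = nuclei
    return cells.astype(np.int32)


def top_fraction_mean(values: np.ndarray, fraction: float = TOP_FRACTION) -> float:
    """Mean of the pixels at or above the (1 - fraction) quantile."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return 0.0
    q = np.quantile(values, 1.0 - fraction)
    return float(values[values >= q].mean())


def phenotype_cells(
    cell_labels: np.ndarray,
    channels: dict[str, np.ndarray],
    pitch_um: float,
    n_clusters: int | None = None,
    seed: int = 0,
    compartment_mask: CompartmentMask | None = None,
    marker_names: dict[str, str] | None = None,
    section: int = 0,
) -> CellTable:
    """Extract top-20% marker features per cell, cluster, and name.

    The per-cell, per-marker feature is the mean of the pixels at or above
    the cell's 80th intensity percentile in that channel (cells smaller
    than 5 pixels fall back to the plain mean and are flagged). Features
    are k-means clustered (``n_clusters`` defaults to the number of
    markers) and each cluster is named after its dominant marker, mapped
    through ``marker_names`` when provided.
    """
    markers = sorted(channels)
    ids = np.unique(cell_labels)
    ids = ids[ids != 0]
    rows = []
    for lb in ids:
        mask = cell_labels == lb
        npx = int(mask.sum())
        ys, xs = np.nonzero(mask)
        cy, cx = ys.mean(), xs.mean()
        small = npx < MIN_PIXELS_FOR_QUANTILE
        feats = []
        for m in markers:
            vals = np.asarray(channels[m], dtype=float)[mask]
            feats.append(float(vals.mean()) if small else top_fraction_mean(vals))
        x_um, y_um = (cx + 0.5) * pitch_um, (cy + 0.5) * pitch_um
        comp = (
            compartment_mask.compartment_of(x_um, y_um)
            if compartment_mask is not None
            else ""
        )
        rows.append([int(lb), x_um, y_um, npx * pitch_um**2, comp, small] + feats)
    df = pd.DataFrame(
        rows,
        columns=["cell_id", "x_um", "y_um", "area_um2", "compartment", "small_cell"]
        + [f"feat_{m}" for m in markers],
    )
    df["section"] = section
    if len(df) == 0:
        df["phenotype"] = pd.Series(dtype=str)
        return CellTable(cells=df, pitch_um=pitch_um)

    from sklearn.cluster import KMeans

    feat_cols = [f"feat_{m}" for m in markers]
    F = df[feat_cols].to_numpy()
    scale = F.max(axis=0)
    scale[scale == 0] = 1.0
    k = n_clusters or len(markers)
    k = min(k, len(df))
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(F / scale)
    df["phenotype_cluster"] = km.labels_

    # dominant-marker naming on scaled cluster centroids
    names = {}
    for c in range(k):
        centroid = km.cluster_centers_[c]
        dom = markers[int(np.argmax(centroid))]
        names[c] = (marker_names or {}).get(dom, f"{dom}+")
    df["phenotype"] = df["phenotype_cluster"].map(names)
    return CellTable(cells=df, pitch_um=pitch_um)
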