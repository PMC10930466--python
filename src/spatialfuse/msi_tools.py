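"""Mass spectrometry imaging: imzML I/O, ion images, adduct annotation.

An :class:`MSIDataset` is a set of centroided per-pixel spectra on a
regular grid (20 um pitch in this workflow). Ion images integrate
intensity inside a ppm window around a target m/z; peak "width" is the
*total* window, i.e. a peak at offset ``|dmz|/mz * 1e6 <= width/2`` is
included. Putative compound annotation derives the neutral mass from each
observed m/z under the standard primary adducts per polarity
([M-H]-, [M]-, [M+Cl]- negative; [M+H]+, [M+Na]+, [M+K]+ positive) and
matches it against a neutral monoisotopic mass table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

# exact masses (u), CODATA / IUPAC standard atomic data
MASS_H = 1.0078250319
MASS_ELECTRON = 0.0005485799
MASS_PROTON = MASS_H - MASS_ELECTRON  # 1.0072764520
MASS_CL = 34.96885268
MASS_NA = 22.98976928
MASS_K = 38.96370649

#: adduct -> (m/z shift from neutral mass M, polarity)
ADDUCTS: dict[str, tuple[float, str]] = {
    "[M-H]-": (-MASS_PROTON, "negative"),
    "[M]-": (+MASS_ELECTRON, "negative"),
    "[M+Cl]-": (+MASS_CL + MASS_ELECTRON, "negative"),
    "[M+H]+": (+MASS_PROTON, "positive"),
    "[M+Na]+": (+MASS_NA - MASS_ELECTRON, "positive"),
    "[M+K]+": (+MASS_K - MASS_ELECTRON, "positive"),
}

#: default total peak-window widths (ppm) by analyte class
DEFAULT_WIDTH_PPM = {"metabolite": 15.0, "glycan": 10.0, "peptide": 10.0}


class ImzMLParseError(ValueError):
    """Malformed imzML/ibd input; message names the fault."""


@dataclass
class MSIDataset:
    """Centroided MSI data on a regular pixel grid.

    ``coords`` is ``(n_pixels, 2)`` of integer ``(x, y)`` pixel indices;
    ``mzs[i]`` / ``intensities[i]`` hold pixel i's spectrum with m/z sorted
    ascending and non-negative intensities.
    """

    coords: np.ndarray
    mzs: list[np.ndarray]
    intensities: list[np.ndarray]
    pixel_pitch_um: float = 20.0
    polarity: str = "negative"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        if len(self.coords) == 0:
            raise ValueError("dataset has no pixels")
        if not (len(self.coords) == len(self.mzs) == len(self.intensities)):
            raise ValueError("coords / spectra length mismatch")
        for i, (mz, it) in enumerate(zip(self.mzs, self.intensities)):
            mz, it = np.asarray(mz, float), np.asarray(it, float)
            if np.any(np.diff(mz) < 0):
                raise ValueError(f"pixel {i}: m/z not sorted ascending")
            if np.any(it < 0):
                raise ValueError(f"pixel {i}: negative intensity")
            self.mzs[i], self.intensities[i] = mz, it

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(ny, nx) covering all pixel indices."""
        return int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1

    def mean_spectrum(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean intensity over pixels on the union of m/z values."""
        all_mz = np.unique(np.concatenate([m for m in self.mzs if len(m)]))
        acc = np.zeros(len(all_mz))
        for mz, it in zip(self.mzs, self.intensities):
            acc[np.searchsorted(all_mz, mz)] += it
        return all_mz, acc / self.n_pixels

    def scaled(self, factor: float) -> "MSIDataset":
        return MSIDataset(
            coords=self.coords.copy(),
            mzs=[m.copy() for m in self.mzs],
            intensities=[i * factor for i in self.intensities],
            pixel_pitch_um=self.pixel_pitch_um,
            polarity=self.polarity,
        )


@dataclass
class PeakList:
    """Selected peaks with per-class default ppm window widths."""

    entries: pd.DataFrame  # columns: mz, width_ppm, analyte_class

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[float, str]] | Sequence[tuple[float, float, str]]
    ) -> "PeakList":
        rows = []
        for rec in records:
            if len(rec) == 2:
                mz, klass = rec
                width = DEFAULT_WIDTH_PPM[klass]
            else:
                mz, width, klass = rec
            rows.append((float(mz), float(width), klass))
        return cls(pd.DataFrame(rows, columns=["mz", "width_ppm", "analyte_class"]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakList":
        df = pd.read_csv(path)
        if "width_ppm" not in df:
            df["width_ppm"] = df["analyte_class"].map(DEFAULT_WIDTH_PPM)
        return cls(df[["mz", "width_ppm", "analyte_class"]])

    def to_csv(self, path: str | Path) -> None:
        self.entries.to_csv(path, index=False)


@dataclass
class IonImage:
    """Raster of windowed intensity around one m/z, on the parent grid."""

    image: np.ndarray  # (ny, nx), NaN where no pixel was measured
    mz: float
    width_ppm: float
    pixel_pitch_um: float

    @property
    def pitch_um(self) -> float:
        return self.pixel_pitch_um


# ---------------------------------------------------------------------------
# imzML I/O (continuous and processed dialects)


def write_imzml(dataset: MSIDataset, path: str | Path) -> None:
    """Serialize to imzML + ibd ('processed' mode: per-pixel m/z axes).

    Pixel coordinates are written 1-based per the imzML convention.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = str(path)
    with ImzMLWriter(path, polarity=dataset.polarity, mode="processed") as w:
        for (x, y), mz, it in zip(dataset.coords, dataset.mzs, dataset.intensities):
            w.addSpectrum(mz, it, (int(x) + 1, int(y) + 1, 1))


def read_imzml(
    path: str | Path, pixel_pitch_um: float = 20.0, polarity: str | None = None
) -> MSIDataset:
    """Parse imzML + ibd (either dialect) into an :class:`MSIDataset`."""
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise ImzMLParseError(f"imzML file not found: {path}")
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise ImzMLParseError(f"missing binary data file: {ibd}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # lxml / struct errors
        raise ImzMLParseError(f"malformed imzML {path}: {exc}") from exc
    coords, mzs, its = [], [], []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, it = parser.getspectrum(i)
        coords.append((int(x) - 1, int(y) - 1))
        order = np.argsort(mz, kind="stable")
        mzs.append(np.asarray(mz, float)[order])
        its.append(np.asarray(it, float)[order])
    if not coords:
        raise ImzMLParseError(f"imzML {path} contains no spectra")
    if polarity is None:
        polarity = getattr(parser, "polarity", None) or "negative"
    return MSIDataset(
        coords=np.array(coords),
        mzs=mzs,
        intensities=its,
        pixel_pitch_um=pixel_pitch_um,
        polarity=polarity,
    )


# ---------------------------------------------------------------------------
# ion images


def extract_ion_image(
    dataset: MSIDataset, mz: float, width_ppm: float
) -> IonImage:
    """Sum per-pixel intensity within a total ppm window around ``mz``.

    A peak at m/z ``m`` contributes iff ``|m - mz| / mz * 1e6 <= width_ppm
    / 2``. Measured pixels with an empty window report 0; grid positions
    never measured are NaN.
    """
    if mz <= 0 or width_ppm <= 0:
        raise ValueError("mz and width must be positive")
    half = mz * width_ppm / 2e6
    ny, nx = dataset.grid_shape
    img = np.full((ny, nx), np.nan)
    for (x, y), pmz, pit in zip(dataset.coords, dataset.mzs, dataset.intensities):
        lo = np.searchsorted(pmz, mz - half, side="left")
        hi = np.searchsorted(pmz, mz + half, side="right")
        img[y, x] = pit[lo:hi].sum()
    return IonImage(
        image=img, mz=mz, width_ppm=width_ppm, pixel_pitch_um=dataset.pixel_pitch_um
    )


def ion_image_to_tiff(ion_image: IonImage, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.nan_to_num(ion_image.image).astype(np.float32))


# ---------------------------------------------------------------------------
# adduct annotation


def annotate_adducts(
    mz_list: Sequence[float],
    compound_masses: pd.DataFrame | dict[str, float],
    polarity: str,
    tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Match observed m/z values to compounds via primary-adduct masses.

    ``compound_masses`` maps compound name -> neutral monoisotopic mass
    (or a DataFrame with ``name`` / ``neutral_mass`` columns). For every
    adduct of the requested polarity the implied neutral mass ``M =
    mz - shift`` is compared against the table; matches within ``tol_ppm``
    are returned sorted by observed m/z then absolute ppm error.
    """
    if polarity not in ("negative", "positive"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if isinstance(compound_masses, dict):
        table = pd.DataFrame(
            {"name": list(compound_masses), "neutral_mass": list(compound_masses.values())}
        )
    else:
        table = compound_masses[["name", "neutral_mass"]]
    rows = []
    for mz in mz_list:
        for adduct, (shift, pol) in ADDUCTS.items():
            if pol != polarity:
                continue
            implied = mz - shift
            ppm = (implied - table["neutral_mass"]) / table["neutral_mass"] * 1e6
            hit = ppm.abs() <= tol_ppm
            for name, mass, err in zip(
                table.loc[hit, "name"], table.loc[hit, "neutral_mass"], ppm[hit]
            ):
                rows.append((mz, adduct, name, mass, float(err)))
    df = pd.DataFrame(
        rows, columns=["observed_mz", "adduct", "compound", "neutral_mass", "ppm_error"]
    )
    return df.sort_values(
        ["observed_mz", "ppm_error"], key=lambda s: s.abs() if s.name == "ppm_error" else s
    ).reset_index(drop=True)


def propose_peaks(
    dataset: MSIDataset, snr: float = 3.0, min_separation: int = 1
) -> np.ndarray:
    """Convenience: local maxima of the mean spectrum above an SNR cut.

    A helper for exploration only; the workflow's peak lists are curated
    inputs.
    """
    from scipy.signal import find_peaks

    mz, mean = dataset.mean_spectrum()
    noise = np.median(mean[mean > 0]) if (mean > 0).any() else 0.0
    idx, _ = find_peaks(mean, height=snr * noise, distance=min_separation)
    return mz[idx]
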