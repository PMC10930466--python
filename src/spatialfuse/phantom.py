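"""Synthetic ground-truth tissue model and modality emitters.

The phantom is a columnar 3D tissue block: a 2D compartment geometry
(tumor disk(s) in stroma by default) extruded through a stack of serial
sections, with cells of ~20 um diameter placed in 3D so that one cell
spans several 5 um sections. From one phantom the three modalities are
emitted with known ground-truth misalignments:

* Stereo-seq paired reads (read 1 = 25 bp CID + 6 bp MID, read 2 = a
  transcript tag), with configurable barcode error and low-quality rates,
  mitochondrial and microbial read fractions, and a per-read truth table;
* MSI pixel spectra at 20 um pitch driven by per-compartment analyte maps;
* seqIF multi-channel images at 0.23 um pitch with DAPI nuclei and
  per-phenotype marker disks.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .msi_tools import MSIDataset
from .reference import MITO_GENES, ConfigurationError, ToyReference
from .stereo_reads import CID_LENGTH, MID_LENGTH, ChipLayout
from .transform import AffineTransform

_BASES = np.array(list("ACGT"))
BACKGROUND = -1


def default_gene_programs(
    n_markers: int = 12, n_shared: int = 36, fold: float = 4.0
) -> dict[str, dict[str, float]]:
    """Two-compartment gene programs with planted markers.

    ``n_markers`` genes per compartment are expressed at ``fold``-times the
    shared baseline rate (fold 4 = planted log2 fold change 2); the panel
    is symmetric so compartment totals match and library-size
    normalization does not compress the planted effect.
    """
    tumor_markers = [f"TUM{i:02d}" for i in range(n_markers)]
    stroma_markers = [f"STR{i:02d}" for i in range(n_markers)]
    shared = [f"HK{i:02d}" for i in range(n_shared)]
    tumor = {g: fold for g in tumor_markers}
    tumor.update({g: 1.0 for g in stroma_markers})
    tumor.update({g: 1.0 for g in shared})
    stroma = {g: 1.0 for g in tumor_markers}
    stroma.update({g: fold for g in stroma_markers})
    stroma.update({g: 1.0 for g in shared})
    return {"tumor": tumor, "stroma": stroma}


def default_analyte_maps() -> dict[str, dict[float, float]]:
    """Per-compartment mean MSI intensities for a few example peaks.

    m/z 1077.361 (glycan) and 136.076 (metabolite) are stroma/interface
    enriched; 958.578 (peptide) is tumor enriched; 140.010 is broadly
    distributed.
    """
    return {
        "tumor": {958.578: 40.0, 140.010: 20.0, 1077.361: 5.0, 136.076: 5.0},
        "stroma": {958.578: 2.0, 140.010: 15.0, 1077.361: 50.0, 136.076: 30.0},
        "interface": {958.578: 25.0, 140.010: 18.0, 1077.361: 40.0, 136.076: 28.0},
    }


@dataclass(frozen=True)
class PhenotypeSpec:
    """A cell phenotype: marker intensity profile and home compartments."""

    name: str
    markers: dict[str, float]
    compartments: tuple[str, ...]
    diameter_um: float = 20.0
    nucleus_diameter_um: float = 10.0


def default_phenotypes() -> tuple[PhenotypeSpec, ...]:
    return (
        PhenotypeSpec("tumor_cell", {"Keratin8/18": 1.0}, ("tumor",)),
        PhenotypeSpec("fibroblast", {"ACTA2": 0.9, "COL1A1": 0.4}, ("stroma",)),
        PhenotypeSpec("immune", {"CD45": 1.0}, ("tumor", "stroma")),
    )


@dataclass
class PhantomConfig:
    """Ground-truth generator configuration.

    ``compartment_spec`` describes the 2D geometry: a background
    compartment plus disks, with an interface band of ``interface
    halfwidth`` um either side of the tumor-stroma boundary. Sections are
    ``section_thickness_um`` thick with centers ``section_spacing_um``
    apart (the every-third-section layout corresponds to 15 um spacing;
    both readings of the sectioning scheme are representable).
    """

    seed: int = 0
    field_size_um: tuple[float, float] = (600.0, 600.0)
    n_sections: int = 3
    section_thickness_um: float = 5.0
    section_spacing_um: float = 10.0
    compartment_spec: dict = field(
        default_factory=lambda: {
            "background": "stroma",
            "disks": [{"compartment": "tumor", "center": (300.0, 300.0), "radius": 240.0}],
            "interface_halfwidth_um": 50.0,
        }
    )
    gene_programs: dict[str, dict[str, float]] = field(default_factory=default_gene_programs)
    mito_fraction: float = 0.01
    microbe_fraction: float = 0.005
    analyte_maps: dict[str, dict[float, float]] = field(default_factory=default_analyte_maps)
    cell_density_per_mm2: dict[str, float] = field(
        default_factory=lambda: {"tumor_cell": 1500.0, "fibroblast": 800.0, "immune": 300.0}
    )
    phenotypes: tuple[PhenotypeSpec, ...] = field(default_factory=default_phenotypes)
    compartment_marker_levels: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            # epithelium is near-confluent for keratin; collagen fills stroma
            "Keratin8/18": {"tumor": 0.4, "interface": 0.2},
            "COL1A1": {"stroma": 0.6, "interface": 0.3},
        }
    )
    misalignment: dict[str, dict] = field(
        default_factory=lambda: {
            "stereo": {"rotation_deg": 0.0, "translation_um": (0.0, 0.0)},
            "msi": {"rotation_deg": 2.0, "translation_um": (12.0, -8.0)},
            "seqif": {"rotation_deg": -1.5, "translation_um": (-6.0, 4.0)},
        }
    )
    barcode_error_rate: float = 0.01
    mid_lowq_rate: float = 0.05
    multimap_gene_fraction: float = 0.05
    label_pitch_um: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mito_fraction", "microbe_fraction", "barcode_error_rate",
                     "mid_lowq_rate", "multimap_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v}")
        if self.field_size_um[0] <= 0 or self.field_size_um[1] <= 0:
            raise ConfigurationError("field size must be positive")
        if self.n_sections < 1:
            raise ConfigurationError("need at least one section")
        if self.section_thickness_um <= 0 or self.section_spacing_um <= 0:
            raise ConfigurationError("section geometry must be positive")

    @property
    def section_z_centers(self) -> np.ndarray:
        """Z center of each section (um), ``section_spacing_um`` apart."""
        first = self.section_thickness_um / 2.0
        return first + self.section_spacing_um * np.arange(self.n_sections)

    @property
    def block_depth_um(self) -> float:
        return float(
            self.section_z_centers[-1] + self.section_thickness_um / 2.0
        )


@dataclass
class Phantom:
    """Realized ground truth: geometry, cells, transforms, reference."""

    config: PhantomConfig
    compartment_field: np.ndarray  # int codes into compartment_names, [y, x]
    interface_mask: np.ndarray  # bool, same raster
    compartment_names: list[str]
    cells: pd.DataFrame  # cell_id, phenotype, x_um, y_um, z_um, diameter_um, ...
    truth_transforms: dict[str, AffineTransform]  # modality um -> reference um
    reference: ToyReference

    @property
    def label_pitch_um(self) -> float:
        return self.config.label_pitch_um

    def compartment_code(self, name: str) -> int:
        return self.compartment_names.index(name)

    def compartment_at(
        self, points_um: np.ndarray, with_interface: bool = True
    ) -> np.ndarray:
        """Compartment code at reference-frame um points (-1 off-field).

        With ``with_interface``, points inside the interface band report
        the ``"interface"`` code when that compartment is modelled.
        """
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        ix = np.floor(pts[:, 0] / self.label_pitch_um).astype(int)
        iy = np.floor(pts[:, 1] / self.label_pitch_um).astype(int)
        h, w = self.compartment_field.shape
        inside = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
        out = np.full(len(pts), BACKGROUND, dtype=int)
        out[inside] = self.compartment_field[iy[inside], ix[inside]]
        if with_interface and "interface" in self.compartment_names:
            icode = self.compartment_code("interface")
            on_iface = np.zeros(len(pts), dtype=bool)
            on_iface[inside] = self.interface_mask[iy[inside], ix[inside]]
            out[on_iface] = icode
        return out

    def cells_in_section(self, section: int) -> pd.DataFrame:
        """Cells whose Z extent intersects the given section's slab."""
        zc = self.config.section_z_centers[section]
        half = self.config.section_thickness_um / 2.0
        lo, hi = zc - half, zc + half
        c = self.cells
        sel = (c["z_um"] + c["diameter_um"] / 2.0 > lo) & (
            c["z_um"] - c["diameter_um"] / 2.0 < hi
        )
        return c[sel].copy()

    def analyte_truth_raster(self, mz: float, pitch_um: float) -> np.ndarray:
        """Reference-frame mean-intensity raster for one m/z peak."""
        w, h = self.config.field_size_um
        nx, ny = int(round(w / pitch_um)), int(round(h / pitch_um))
        xs = (np.arange(nx) + 0.5) * pitch_um
        ys = (np.arange(ny) + 0.5) * pitch_um
        gx, gy = np.meshgrid(xs, ys)
        codes = self.compartment_at(np.column_stack([gx.ravel(), gy.ravel()]))
        img = np.zeros(codes.shape, dtype=float)
        for name, peaks in self.config.analyte_maps.items():
            if name in self.compartment_names and mz in peaks:
                img[codes == self.compartment_code(name)] = peaks[mz]
        return img.reshape(ny, nx)

    def truth_manifest(self) -> dict:
        """JSON-serializable record of the generator truth."""
        cfg = dataclasses.asdict(self.config)
        cfg["phenotypes"] = [dataclasses.asdict(p) for p in self.config.phenotypes]
        return {
            "config": cfg,
            "compartment_names": self.compartment_names,
            "transforms": {k: t.to_json_dict() for k, t in self.truth_transforms.items()},
            "cells": self.cells.to_dict(orient="list"),
        }

    def save_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_manifest(), fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# phantom construction


def make_phantom(config: PhantomConfig) -> Phantom:
    """Build the ground-truth tissue model from a configuration.

    The compartment raster covers the full field at ``label_pitch_um``;
    the interface ground truth is the set of pixels within the configured
    halfwidth of the tumor-stroma (disk) boundary. Deterministic given
    ``config.seed``.
    """
    pitch = config.label_pitch_um
    w_um, h_um = config.field_size_um
    nx, ny = int(round(w_um / pitch)), int(round(h_um / pitch))

    spec = config.compartment_spec
    names = [spec["background"]]
    for d in spec.get("disks", []):
        if d["compartment"] not in names:
            names.append(d["compartment"])
    for prog in config.gene_programs:
        if prog not in names and prog != "interface":
            names.append(prog)
    field_arr = np.zeros((ny, nx), dtype=np.int16)  # background = code 0
    xs = (np.arange(nx) + 0.5) * pitch
    ys = (np.arange(ny) + 0.5) * pitch
    gx, gy = np.meshgrid(xs, ys)
    for d in spec.get("disks", []):
        code = names.index(d["compartment"])
        cx, cy = d["center"]
        field_arr[(gx - cx) ** 2 + (gy - cy) ** 2 <= d["radius"] ** 2] = code

    for i, name in enumerate(names):
        if name in config.gene_programs and not (field_arr == i).any():
            raise ConfigurationError(f"compartment {name!r} has zero area")

    hw = spec.get("interface_halfwidth_um", 50.0)
    fg = field_arr != 0
    if fg.any() and (~fg).any():
        d_to_fg = distance_transform_edt(~fg) * pitch
        d_to_bg = distance_transform_edt(fg) * pitch
        interface = (d_to_fg <= hw) & (d_to_bg <= hw)
    else:
        interface = np.zeros_like(fg)
    if "interface" in config.gene_programs or "interface" in config.analyte_maps:
        if "interface" not in names:
            names.append("interface")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    cells = _place_cells(config, field_arr, interface, names, rng)

    transforms = {}
    for modality in sorted(config.misalignment):
        p = config.misalignment[modality]
        transforms[modality] = AffineTransform.from_params(
            rotation_deg=p.get("rotation_deg", 0.0),
            translation=tuple(p.get("translation_um", (0.0, 0.0))),
        )

    host = sorted(
        {g for prog in config.gene_programs.values() for g in prog}
    )
    # multi-mapping tags are drawn from genes expressed at the same rate in
    # every compartment, so the MAPQ filter never hides a planted marker
    progs = list(config.gene_programs.values())
    uniform = [
        g for g in host
        if len({p.get(g) for p in progs}) == 1 and progs[0].get(g) is not None
    ]
    n_multi = int(round(config.multimap_gene_fraction * len(host)))
    pool = uniform if len(uniform) >= n_multi else host
    multimap = frozenset(pool[-n_multi:]) if n_multi else frozenset()
    reference = ToyReference(
        host_genes=tuple(host), multimapping_genes=multimap, mito_genes=MITO_GENES
    )
    return Phantom(
        config=config,
        compartment_field=field_arr,
        interface_mask=interface,
        compartment_names=names,
        cells=cells,
        truth_transforms=transforms,
        reference=reference,
    )


def _place_cells(
    config: PhantomConfig,
    field_arr: np.ndarray,
    interface: np.ndarray,
    names: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    pitch = config.label_pitch_um
    depth = config.block_depth_um
    rows = []
    cell_id = 0
    for pheno in config.phenotypes:
        density = config.cell_density_per_mm2.get(pheno.name, 0.0)
        if density <= 0:
            continue
        mask = np.zeros_like(field_arr, dtype=bool)
        for comp in pheno.compartments:
            if comp == "interface":
                mask |= interface
            elif comp in names:
                mask |= field_arr == names.index(comp)
        if not mask.any():
            continue
        area_mm2 = mask.sum() * pitch**2 / 1e6
        n = rng.poisson(density * area_mm2)
        iy, ix = np.nonzero(mask)
        pick = rng.integers(0, len(ix), n)
        x_um = (ix[pick] + rng.random(n)) * pitch
        y_um = (iy[pick] + rng.random(n)) * pitch
        z_um = rng.uniform(0.0, depth, n)
        for k in range(n):
            rows.append(
                (cell_id, pheno.name, x_um[k], y_um[k], z_um[k],
                 pheno.diameter_um, pheno.nucleus_diameter_um)
            )
            cell_id += 1
    return pd.DataFrame(
        rows,
        columns=["cell_id", "phenotype", "x_um", "y_um", "z_um",
                 "diameter_um", "nucleus_diameter_um"],
    )


# ---------------------------------------------------------------------------
# chip layout emission


def _random_barcodes(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=(n, CID_LENGTH), dtype=np.int8)


def _min_pairwise_hamming_ok(codes: np.ndarray, min_dist: int) -> np.ndarray:
    """Boolean per row: at min. ``min_dist`` from every earlier-kept row."""
    n = len(codes)
    keep = np.ones(n, dtype=bool)
    chunk = 512
    for start in range(0, n, chunk):
        block = codes[start : start + chunk]
        # distances to all rows before this block that are kept
        prev = codes[:start][keep[:start]]
        if len(prev):
            d = (block[:, None, :] != prev[None, :, :]).sum(axis=2)
            bad = (d < min_dist).any(axis=1)
        else:
            bad = np.zeros(len(block), dtype=bool)
        # within-block pairwise
        din = (block[:, None, :] != block[None, :, :]).sum(axis=2)
        np.fill_diagonal(din, CID_LENGTH)
        for i in range(len(block)):
            if bad[i]:
                continue
            close = (din[i, :i] < min_dist) & ~bad[:i]
            if close.any():
                bad[i] = True
        keep[start : start + len(block)] = ~bad
    return keep


def emit_chip_layout(
    n_spots_x: int,
    n_spots_y: int,
    pitch_um: float = 0.5,
    seed: int = 0,
    min_hamming: int = 3,
    enforce_hamming_max_n: int = 10_000,
) -> ChipLayout:
    """Generate a full-grid chip layout with distinct 25-mer barcodes.

    For layouts up to ``enforce_hamming_max_n`` spots the generator
    enforces a minimum pairwise Hamming distance of ``min_hamming`` so that
    one-mismatch CID correction is unambiguous; offending barcodes are
    re-drawn. Larger layouts rely on the vanishing collision probability
    of random 25-mers (guaranteed distinct either way).
    """
    if pitch_um <= 0:
        raise ValueError("pitch must be positive")
    n = n_spots_x * n_spots_y
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1A9]))
    codes = _random_barcodes(n, rng)
    if n <= enforce_hamming_max_n:
        for _ in range(50):
            keep = _min_pairwise_hamming_ok(codes, min_hamming)
            if keep.all():
                break
            codes[~keep] = _random_barcodes((~keep).sum(), rng)
        else:
            raise RuntimeError("could not satisfy barcode separation")
    seqs = ["".join(row) for row in _BASES[codes]]
    if len(set(seqs)) != n:  # pragma: no cover - astronomically unlikely >1e4
        raise RuntimeError("duplicate barcodes generated")
    barcodes = {}
    k = 0
    for y in range(n_spots_y):
        for x in range(n_spots_x):
            barcodes[seqs[k]] = (x, y)
            k += 1
    return ChipLayout(barcodes=barcodes, pitch_um=pitch_um)


# ---------------------------------------------------------------------------
# stereo-seq read emission


@dataclass
class StereoReads:
    """Synthetic paired reads plus the per-read ground-truth table."""

    read1: list[tuple[str, list[int]]]  # (sequence, phred qualities)
    read2: list[str]
    truth: pd.DataFrame  # read, x_index, y_index, category, name, mid, cid_errors

    def __len__(self) -> int:
        return len(self.read1)

    def pairs(self):
        """Iterate ``(seq1, qual1, seq2)`` as consumed by demultiplexing."""
        for (s1, q1), s2 in zip(self.read1, self.read2):
            yield s1, q1, s2

    def write_fastq(self, read1_path: str | Path, read2_path: str | Path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        recs1, recs2 = [], []
        for i, ((s1, q1), s2) in enumerate(zip(self.read1, self.read2)):
            recs1.append(
                SeqRecord(Seq(s1), id=f"read{i}", description="",
                          letter_annotations={"phred_quality": list(q1)})
            )
            recs2.append(
                SeqRecord(Seq(s2), id=f"read{i}", description="",
                          letter_annotations={"phred_quality": [30] * len(s2)})
            )
        seqio_write(recs1, str(read1_path), "fastq")
        seqio_write(recs2, str(read2_path), "fastq")


def emit_stereo_reads(
    phantom: Phantom,
    section: int,
    layout: ChipLayout,
    depth: float = 1.0,
    config: PhantomConfig | None = None,
) -> StereoReads:
    """Emit paired reads for one section at ``depth`` reads per spot.

    Each read draws its transcript from the spot's compartment gene
    program, or a mitochondrial / microbial tag at the configured
    fractions. Barcode errors substitute one CID base at
    ``barcode_error_rate``; MID base qualities are Q30 with Q8 lows at
    ``mid_lowq_rate``. The truth table has one row per emitted pair.
    """
    config = config or phantom.config
    if not 0 <= section < config.n_sections:
        raise ValueError(f"section {section} out of range")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EAD, section]))

    ref = phantom.reference
    spots = sorted(layout.barcodes.items(), key=lambda kv: kv[1])
    spot_xy = np.array([xy for _, xy in spots])
    spot_um = spot_xy * layout.pitch_um
    codes = phantom.compartment_at(
        spot_um, with_interface="interface" in config.gene_programs
    )

    # per-compartment gene samplers (interface falls back through programs)
    prog_names = list(config.gene_programs)
    samplers = {}
    for name in prog_names:
        genes = sorted(config.gene_programs[name])
        p = np.array([config.gene_programs[name][g] for g in genes], dtype=float)
        samplers[phantom.compartment_code(name) if name in phantom.compartment_names
                 else None] = (genes, p / p.sum())
    fallback = samplers[phantom.compartment_code(prog_names[0])]

    base = int(np.floor(depth))
    n_per_spot = base + (rng.random(len(spots)) < depth - base)
    total = int(n_per_spot.sum())

    read1, read2, truth_rows = [], [], []
    mito_genes = list(ref.mito_genes)
    taxa = sorted(ref.taxa)
    read_idx = 0
    for s, (bc, (x, y)) in enumerate(spots):
        n = int(n_per_spot[s])
        if n == 0:
            continue
        genes, probs = samplers.get(codes[s], fallback)
        u = rng.random(n)
        gene_choice = rng.choice(len(genes), size=n, p=probs)
        mito_choice = rng.integers(0, len(mito_genes), n)
        taxon_choice = rng.integers(0, len(taxa), n)
        mids_int = rng.integers(0, 4, size=(n, MID_LENGTH))
        lowq = rng.random((n, MID_LENGTH)) < config.mid_lowq_rate
        bc_err = rng.random(n) < config.barcode_error_rate
        err_pos = rng.integers(0, CID_LENGTH, n)
        err_shift = rng.integers(1, 4, n)
        for k in range(n):
            if u[k] < config.mito_fraction:
                category, name = "mito", mito_genes[mito_choice[k]]
            elif u[k] < config.mito_fraction + config.microbe_fraction:
                category, name = "microbe", taxa[taxon_choice[k]]
            else:
                category, name = "host", genes[gene_choice[k]]
            mid = "".join(_BASES[mids_int[k]])
            cid = bc
            nerr = 0
            if bc_err[k]:
                pos = int(err_pos[k])
                orig = "ACGT".index(cid[pos])
                cid = cid[:pos] + "ACGT"[(orig + err_shift[k]) % 4] + cid[pos + 1 :]
                nerr = 1
            qual = [30] * CID_LENGTH + [8 if lq else 30 for lq in lowq[k]]
            read1.append((cid + mid, qual))
            read2.append(ref.tag(name))
            truth_rows.append((read_idx, x, y, category, name, mid, nerr))
            read_idx += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=["read", "x_index", "y_index", "category", "name", "mid", "cid_errors"],
    )
    assert len(truth) == total
    return StereoReads(read1=read1, read2=read2, truth=truth)


# ---------------------------------------------------------------------------
# MSI emission


def emit_msi(
    phantom: Phantom,
    section: int,
    peak_mzs: Sequence[float],
    pixel_pitch_um: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MSIDataset:
    """Emit one section's MSI dataset on a 20 um (default) pixel grid.

    Pixel centers are mapped through the MSI ground-truth affine into the
    reference frame and each peak's intensity is the compartment's analyte
    level plus Gaussian noise (clipped at 0). Off-tissue pixels are 0.
    """
    if len(peak_mzs) == 0:
        raise ValueError("peak list must be non-empty")
    cfg = phantom.config
    w_um, h_um = cfg.field_size_um
    nx, ny = int(round(w_um / pixel_pitch_um)), int(round(h_um / pixel_pitch_um))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x351, section]))
    T = phantom.truth_transforms.get("msi", AffineTransform.identity())

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny))
    px_um = np.column_stack([(ii.ravel() + 0.5), (jj.ravel() + 0.5)]) * pixel_pitch_um
    ref_um = T.apply(px_um)
    codes = phantom.compartment_at(ref_um)

    mz_arr = np.array(sorted(peak_mzs), dtype=float)
    level = np.zeros((len(codes), len(mz_arr)))
    for name, peaks in cfg.analyte_maps.items():
        if name not in phantom.compartment_names:
            continue
        sel = codes == phantom.compartment_code(name)
        for j, mz in enumerate(mz_arr):
            if mz in peaks:
                level[sel, j] = peaks[mz]
    if noise_sd > 0:
        level = level + rng.normal(0.0, noise_sd, size=level.shape)
    level = np.clip(level, 0.0, None)

    coords = np.column_stack([ii.ravel(), jj.ravel()]).astype(int)
    return MSIDataset(
        coords=coords,
        mzs=[mz_arr.copy() for _ in range(len(coords))],
        intensities=[level[i] for i in range(len(coords))],
        pixel_pitch_um=pixel_pitch_um,
        polarity="negative",
    )


# ---------------------------------------------------------------------------
# seqIF emission


def emit_seqif(
    phantom: Phantom,
    section: int,
    markers: Sequence[str],
    pixel_pitch_um: float = 0.23,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[list[str], np.ndarray]:
    """Render one section's multi-channel immunofluorescence image.

    Returns ``(channel_names, image)`` with ``image`` of shape
    ``(n_channels, ny, nx)`` float32 in the seqIF pixel frame (ground-truth
    affine applied). DAPI renders nucleus disks for every cell present in
    the section; marker channels render whole-cell disks at each
    phenotype's profile level plus any compartment-level marker signal.
    """
    if "DAPI" not in markers:
        raise ValueError("marker list must include DAPI")
    cfg = phantom.config
    w_um, h_um = cfg.field_size_um
    nx, ny = int(round(w_um / pixel_pitch_um)), int(round(h_um / pixel_pitch_um))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E9, section]))
    T = phantom.truth_transforms.get("seqif", AffineTransform.identity())
    Tinv = T.inverse()

    img = np.zeros((len(markers), ny, nx), dtype=np.float32)
    marker_idx = {m: i for i, m in enumerate(markers)}

    # compartment-level signal (e.g. collagen over stroma)
    comp_levels = {
        m: lv for m, lv in cfg.compartment_marker_levels.items() if m in marker_idx
    }
    if comp_levels:
        ii, jj = np.meshgrid(np.arange(nx), np.arange(ny))
        px_um = np.column_stack([ii.ravel() + 0.5, jj.ravel() + 0.5]) * pixel_pitch_um
        codes = phantom.compartment_at(T.apply(px_um)).reshape(ny, nx)
        for m, levels in comp_levels.items():
            ch = img[marker_idx[m]]
            for comp, lv in levels.items():
                if comp in phantom.compartment_names:
                    ch[codes == phantom.compartment_code(comp)] += lv

    from skimage.draw import disk as draw_disk

    profiles = {p.name: p for p in cfg.phenotypes}
    cells = phantom.cells_in_section(section)
    for row in cells.itertuples():
        px = Tinv.apply(np.array([row.x_um, row.y_um])) / pixel_pitch_um - 0.5
        cx, cy = float(px[0]), float(px[1])
        r_cell = row.diameter_um / 2.0 / pixel_pitch_um
        r_nuc = row.nucleus_diameter_um / 2.0 / pixel_pitch_um
        rr, cc = draw_disk((cy, cx), max(r_nuc, 1.0), shape=(ny, nx))
        img[marker_idx["DAPI"], rr, cc] = 1.0
        prof = profiles.get(row.phenotype)
        if prof is None:
            continue
        rr, cc = draw_disk((cy, cx), max(r_cell, 1.0), shape=(ny, nx))
        for m, lv in prof.markers.items():
            if m in marker_idx:
                img[marker_idx[m], rr, cc] = np.maximum(img[marker_idx[m], rr, cc], lv)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
        np.clip(img, 0.0, None, out=img)
    return list(markers), img
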