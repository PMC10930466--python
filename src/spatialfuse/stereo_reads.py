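"""Spatial transcriptomics read processing.

Turns paired reads plus a chip layout into a spot-level expression matrix.
Read 1 carries the spatial barcode (CID, bases 1-25) and the molecular
identifier (MID/UMI, bases 26-31); read 2 carries the transcript sequence.
The processing rules are:

* CID matched exactly against the chip layout, else corrected to a unique
  Hamming-distance-1 neighbour; ambiguous or unmatched CIDs are rejected.
* MIDs containing N, or more than 2 bases with quality < 10, are rejected.
* Transcript hits with MAPQ <= 10 are discarded; non-host hits are tallied
  per taxonomic class; MIDs are collapsed per (spot, gene) allowing one
  mismatch (connected components of the Hamming<=1 graph).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO

from .reference import ConfigurationError, ToyReference

CID_LENGTH = 25
MID_LENGTH = 6
READ1_LENGTH = CID_LENGTH + MID_LENGTH
MIN_MAPQ = 10  # hits must have MAPQ strictly greater than this
LOW_QUAL = 10  # MID bases with quality strictly below this count as low
MAX_LOW_QUAL_BASES = 2
BIN200 = 200

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# chip layout


@dataclass
class ChipLayout:
    """Map from 25-mer spatial barcodes to spot grid indices.

    Spot indices are 0-based; physical position is ``index * pitch_um``.
    """

    barcodes: dict[str, tuple[int, int]]
    pitch_um: float

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")
        for bc, (x, y) in self.barcodes.items():
            if len(bc) != CID_LENGTH:
                raise ValueError(f"barcode {bc!r} is not a {CID_LENGTH}-mer")
            if x < 0 or y < 0:
                raise ValueError("grid indices must be non-negative")

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(bc, x, y) for bc, (x, y) in self.barcodes.items()],
            columns=["barcode", "x_index", "y_index"],
        )
        with open(path, "w") as fh:
            fh.write(f"# pitch_um={self.pitch_um}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChipLayout":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# pitch_um="):
                raise ValueError("layout TSV missing '# pitch_um=' header line")
            pitch = float(header.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t")
        return cls(
            {r.barcode: (int(r.x_index), int(r.y_index)) for r in df.itertuples()},
            pitch_um=pitch,
        )


# ---------------------------------------------------------------------------
# demultiplexing


class DemuxResult(NamedTuple):
    spot: tuple[int, int] | None
    mid: str | None
    reason: str | None  # None = accepted; else "cid" | "mid" | "short"


def _hamming1_neighbors(seq: str) -> Iterator[str]:
    for i, orig in enumerate(seq):
        for b in _BASES:
            if b != orig:
                yield seq[:i] + b + seq[i + 1 :]


def demultiplex_read1(
    seq: str, qual: Iterable[int], layout: ChipLayout
) -> DemuxResult:
    """Resolve read 1 to a chip spot and MID.

    Exact CID match wins; otherwise a *unique* Hamming-1 neighbour present
    in the layout is accepted (one-mismatch correction); zero or several
    neighbours reject the read. The MID is rejected if it contains N or has
    more than 2 bases with quality below 10.
    """
    if len(seq) < READ1_LENGTH:
        return DemuxResult(None, None, "short")
    cid = seq[:CID_LENGTH]
    mid = seq[CID_LENGTH:READ1_LENGTH]
    spot = layout.barcodes.get(cid)
    if spot is None:
        hits = [
            s
            for nb in _hamming1_neighbors(cid)
            if (s := layout.barcodes.get(nb)) is not None
        ]
        if len(hits) != 1:
            return DemuxResult(None, None, "cid")
        spot = hits[0]
    if "N" in mid:
        return DemuxResult(None, None, "mid")
    mid_qual = list(qual)[CID_LENGTH:READ1_LENGTH]
    if sum(q < LOW_QUAL for q in mid_qual) > MAX_LOW_QUAL_BASES:
        return DemuxResult(None, None, "mid")
    return DemuxResult(spot, mid, None)


def assign_gene(
    read2_seq: str, reference: ToyReference
) -> tuple[str, str | None, int | None]:
    """Assign read 2 to ``(status, name, mapq)``.

    Status is ``"gene"`` (host or mitochondrial hit with MAPQ > 10),
    ``"low_mapq"`` (host hit discarded by the MAPQ filter), ``"taxon"``
    (non-host hit, name is the species), or ``"unassigned"``.
    """
    if reference is None:
        raise ConfigurationError("reference is required")
    hit = reference.lookup(read2_seq)
    if hit is None:
        return ("unassigned", None, None)
    kind, name, mapq = hit
    if kind == "microbe":
        return ("taxon", name, None)
    if mapq > MIN_MAPQ:
        return ("gene", name, mapq)
    return ("low_mapq", name, mapq)


def process_read_pairs(
    pairs: Iterable[tuple[str, Iterable[int], str]],
    layout: ChipLayout,
    reference: ToyReference,
) -> pd.DataFrame:
    """Demultiplex and assign an iterable of ``(seq1, qual1, seq2)`` tuples.

    Returns one row per read with columns ``status`` (gene / low_mapq /
    taxon / unassigned / rejected_cid / rejected_mid / rejected_short),
    ``x_index``, ``y_index``, ``mid``, ``name``, ``mapq``. The rows
    partition the input: every read appears exactly once.
    """
    rows = []
    for seq1, qual1, seq2 in pairs:
        spot, mid, reason = demultiplex_read1(seq1, qual1, layout)
        if reason is not None:
            rows.append((f"rejected_{reason}", -1, -1, mid, None, np.nan))
            continue
        status, name, mapq = assign_gene(seq2, reference)
        rows.append(
            (status, spot[0], spot[1], mid, name, np.nan if mapq is None else mapq)
        )
    return pd.DataFrame(
        rows, columns=["status", "x_index", "y_index", "mid", "name", "mapq"]
    )


# ---------------------------------------------------------------------------
# UMI collapse


def collapse_umis(mids: Iterable[str]) -> int:
    """Count molecules at one (spot, gene) locus, allowing 1 mismatch.

    The count is the number of connected components of the graph whose
    vertices are the distinct MIDs and whose edges join MIDs at Hamming
    distance <= 1.
    """
    distinct = set(mids)
    if not distinct:
        return 0
    for m in distinct:
        if len(m) != MID_LENGTH or any(b not in _BASES for b in m):
            raise ValueError(f"invalid MID {m!r}")
    index = {m: i for i, m in enumerate(distinct)}
    parent = list(range(len(index)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for m, i in index.items():
        for nb in _hamming1_neighbors(m):
            j = index.get(nb)
            if j is not None:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(len(index))})


# ---------------------------------------------------------------------------
# expression matrix


@dataclass
class SpotExpression:
    """Sparse spot x gene MID-collapsed count matrix with spot coordinates.

    ``genes`` includes mitochondrial genes, flagged by ``mito_gene_mask``;
    ``spots`` carries grid indices, physical positions, and the number of
    demultiplexed reads per spot. ``microbe_counts`` is indexed by
    taxonomic class.
    """

    counts: sp.csr_matrix
    genes: list[str]
    spots: pd.DataFrame
    mito_gene_mask: np.ndarray
    microbe_counts: pd.Series
    pitch_um: float
    section: int = 0

    def __post_init__(self) -> None:
        if self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def mito_counts(self) -> np.ndarray:
        """Per-spot MID count over mitochondrial genes."""
        if not self.mito_gene_mask.any():
            return np.zeros(self.counts.shape[0], dtype=int)
        return np.asarray(
            self.counts[:, self.mito_gene_mask].sum(axis=1)
        ).ravel()

    @property
    def host_counts(self) -> np.ndarray:
        return np.asarray(self.counts[:, ~self.mito_gene_mask].sum(axis=1)).ravel()

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=self.spots.reset_index(drop=True).copy(),
            var=pd.DataFrame(
                {"is_mito": self.mito_gene_mask}, index=pd.Index(self.genes, name="gene")
            ),
        )
        adata.obs["section"] = self.section
        adata.uns["pitch_um"] = self.pitch_um
        return adata

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(outdir / "matrix.mtx", self.counts)
        self.spots.to_csv(outdir / "spots.tsv", sep="\t", index=False)
        pd.DataFrame({"gene": self.genes, "is_mito": self.mito_gene_mask}).to_csv(
            outdir / "genes.tsv", sep="\t", index=False
        )
        self.microbe_counts.rename_axis("taxon_class").rename("mid_count").to_csv(
            outdir / "microbes.csv"
        )
        pd.Series({"pitch_um": self.pitch_um, "section": self.section}).to_json(
            outdir / "meta.json"
        )

    @classmethod
    def load(cls, outdir: str | Path) -> "SpotExpression":
        outdir = Path(outdir)
        counts = sp.csr_matrix(scipy.io.mmread(outdir / "matrix.mtx"))
        spots = pd.read_csv(outdir / "spots.tsv", sep="\t")
        genes = pd.read_csv(outdir / "genes.tsv", sep="\t")
        microbes = pd.read_csv(outdir / "microbes.csv", index_col=0)["mid_count"]
        meta = pd.read_json(outdir / "meta.json", typ="series")
        return cls(
            counts=counts,
            genes=genes["gene"].tolist(),
            spots=spots,
            mito_gene_mask=genes["is_mito"].to_numpy(),
            microbe_counts=microbes,
            pitch_um=float(meta["pitch_um"]),
            section=int(meta["section"]),
        )


def build_matrix(
    assignments: pd.DataFrame,
    layout: ChipLayout,
    reference: ToyReference,
    section: int = 0,
) -> SpotExpression:
    """Aggregate per-read assignments into a :class:`SpotExpression`.

    MIDs are collapsed per (spot, gene) and per (spot, species); the matrix
    holds one row per spot that received at least one demultiplexed read.
    """
    demuxed = assignments[~assignments["status"].str.startswith("rejected")]
    spot_keys = sorted(
        {(int(x), int(y)) for x, y in zip(demuxed["x_index"], demuxed["y_index"])}
    )
    spot_index = {k: i for i, k in enumerate(spot_keys)}
    genes = list(reference.all_genes)
    gene_index = {g: j for j, g in enumerate(genes)}
    mito_set = set(reference.mito_genes)

    locus_mids: dict[tuple[int, int], list[str]] = defaultdict(list)
    taxon_mids: dict[tuple[int, str], list[str]] = defaultdict(list)
    for row in demuxed.itertuples():
        i = spot_index[(int(row.x_index), int(row.y_index))]
        if row.status == "gene":
            locus_mids[(i, gene_index[row.name])].append(row.mid)
        elif row.status == "taxon":
            taxon_mids[(i, row.name)].append(row.mid)

    data, ri, ci = [], [], []
    for (i, j), mids in locus_mids.items():
        data.append(collapse_umis(mids))
        ri.append(i)
        ci.append(j)
    counts = sp.csr_matrix(
        (data, (ri, ci)), shape=(len(spot_keys), len(genes)), dtype=np.int64
    )

    class_counts: dict[str, int] = defaultdict(int)
    for (i, species), mids in taxon_mids.items():
        class_counts[reference.taxon_class(species)] += collapse_umis(mids)

    reads_per_spot = demuxed.groupby(["x_index", "y_index"]).size()
    spots = pd.DataFrame(spot_keys, columns=["x_index", "y_index"])
    spots["x_um"] = spots["x_index"] * layout.pitch_um
    spots["y_um"] = spots["y_index"] * layout.pitch_um
    spots["n_reads"] = [
        int(reads_per_spot.get((x, y), 0)) for x, y in spot_keys
    ]
    return SpotExpression(
        counts=counts,
        genes=genes,
        spots=spots,
        mito_gene_mask=np.array([g in mito_set for g in genes]),
        microbe_counts=pd.Series(class_counts, dtype=np.int64).sort_index(),
        pitch_um=layout.pitch_um,
        section=section,
    )


# ---------------------------------------------------------------------------
# QC summary


@dataclass
class QCSummary:
    """Chip-level quality metrics over 100 um x 100 um (bin200) tiles."""

    mid_under_tissue_pct: float
    median_reads_per_bin200: float
    median_mid_per_bin200: float
    median_gene_types_per_bin200: float
    mito_pct: float
    microbiome_transcripts: int

    def __post_init__(self) -> None:
        for pct in (self.mid_under_tissue_pct, self.mito_pct):
            if not 0.0 <= pct <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def qc_summary(matrix: SpotExpression, tissue_mask: np.ndarray) -> QCSummary:
    """Summarize a :class:`SpotExpression` against a tissue mask.

    ``tissue_mask`` is boolean, indexed ``[y_index, x_index]`` on the spot
    grid. Medians are taken over bin200 tiles containing at least one
    masked spot.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.sum() == 0:
        raise ValueError("tissue mask is empty")
    xs = matrix.spots["x_index"].to_numpy()
    ys = matrix.spots["y_index"].to_numpy()
    inb = (ys < tissue_mask.shape[0]) & (xs < tissue_mask.shape[1])
    under = np.zeros(len(xs), dtype=bool)
    under[inb] = tissue_mask[ys[inb], xs[inb]]

    mid_per_spot = np.asarray(matrix.counts.sum(axis=1)).ravel()
    total_mid = mid_per_spot.sum()
    mid_under_pct = 100.0 * mid_per_spot[under].sum() / total_mid if total_mid else 0.0

    bx, by = xs // BIN200, ys // BIN200
    bins = pd.DataFrame({"bx": bx, "by": by, "under": under})
    tissue_bins = set(map(tuple, bins.loc[under, ["bx", "by"]].drop_duplicates().values))
    in_tissue_bin = np.array([(x, y) in tissue_bins for x, y in zip(bx, by)])

    grp = pd.DataFrame(
        {
            "bx": bx[in_tissue_bin],
            "by": by[in_tissue_bin],
            "reads": matrix.spots["n_reads"].to_numpy()[in_tissue_bin],
            "mid": mid_per_spot[in_tissue_bin],
        }
    ).groupby(["bx", "by"])
    per_bin = grp.sum()

    # distinct genes per bin: aggregate the sparse matrix by bin
    coo = matrix.counts.tocoo()
    keep = in_tissue_bin[coo.row]
    bin_ids = {b: i for i, b in enumerate(sorted(tissue_bins))}
    rows = [bin_ids[(bx[r], by[r])] for r in coo.row[keep]]
    binned = sp.csr_matrix(
        (coo.data[keep], (rows, coo.col[keep])),
        shape=(len(bin_ids), matrix.counts.shape[1]),
    )
    gene_types = np.asarray((binned > 0).sum(axis=1)).ravel()

    mito = matrix.mito_counts.sum()
    host = matrix.host_counts.sum()
    mito_pct = 100.0 * mito / (mito + host) if (mito + host) else 0.0
    return QCSummary(
        mid_under_tissue_pct=float(mid_under_pct),
        median_reads_per_bin200=float(np.median(per_bin["reads"])) if len(per_bin) else 0.0,
        median_mid_per_bin200=float(np.median(per_bin["mid"])) if len(per_bin) else 0.0,
        median_gene_types_per_bin200=float(np.median(gene_types)) if len(gene_types) else 0.0,
        mito_pct=float(mito_pct),
        microbiome_transcripts=int(matrix.microbe_counts.sum()),
    )


# ---------------------------------------------------------------------------
# FASTQ I/O


def read_fastq_pairs(
    read1_path: str | Path, read2_path: str | Path
) -> Iterator[tuple[str, list[int], str]]:
    """Yield ``(seq1, qual1, seq2)`` from paired FASTQ files."""
    it1 = SeqIO.parse(str(read1_path), "fastq")
    it2 = SeqIO.parse(str(read2_path), "fastq")
    for r1, r2 in zip(it1, it2, strict=True):
        yield str(r1.seq), r1.letter_annotations["phred_quality"], str(r2.seq)
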