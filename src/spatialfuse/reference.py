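"""Toy tag-based sequence reference.

Real alignment of cDNA reads against a genome is out of scope here: read 2
of every synthetic read pair carries an exact 40-base *tag* that identifies
a transcript (host gene, mitochondrial gene, or microbial taxon).
Assignment is a dictionary lookup, but the downstream contract mirrors a
real aligner: host hits carry a MAPQ, multi-mapping tags are emitted with
MAPQ 0 and are discarded by the ``MAPQ > 10`` rule, and non-host hits are
routed to a taxon partition keyed by taxonomic class.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

TAG_LENGTH = 40
BASES = np.array(list("ACGT"))

#: Small fixed toy taxonomy: species -> taxonomic class. The classes mirror
#: the dominant classes reported for tumor-resident microbes.
TOY_TAXONOMY: dict[str, str] = {
    "Escherichia_coli": "Gammaproteobacteria",
    "Pseudomonas_aeruginosa": "Gammaproteobacteria",
    "Cutibacterium_acnes": "Actinomycetia",
    "Corynebacterium_striatum": "Actinomycetia",
    "Malassezia_restricta": "Malasseziomycetes",
}

MITO_GENES = ("MT-CO1", "MT-ND1", "MT-CYB", "MT-RNR2")


def _tag_for(name: str) -> str:
    """Deterministic pseudo-random 40-mer derived from the entry name."""
    rng = np.random.default_rng(zlib.crc32(name.encode()))
    return "".join(BASES[rng.integers(0, 4, TAG_LENGTH)])


class ConfigurationError(ValueError):
    """Invalid reference or generator configuration."""


@dataclass
class ToyReference:
    """Lookup table from read-2 tag sequences to genes or taxa.

    Parameters
    ----------
    host_genes
        Nuclear gene names (includes planted compartment markers).
    multimapping_genes
        Subset of host genes whose tags are reported with MAPQ 0, standing
        in for reads that align to multiple loci.
    mito_genes
        Mitochondrial gene names; host genes flagged as mitochondrial.
    taxa
        Mapping species -> taxonomic class for non-host tags.
    """

    host_genes: tuple[str, ...]
    multimapping_genes: frozenset[str] = frozenset()
    mito_genes: tuple[str, ...] = MITO_GENES
    taxa: dict[str, str] = field(default_factory=lambda: dict(TOY_TAXONOMY))
    unique_mapq: int = 255

    def __post_init__(self) -> None:
        if not self.host_genes and not self.mito_genes:
            raise ConfigurationError("reference has no host genes")
        unknown = set(self.multimapping_genes) - set(self.host_genes)
        if unknown:
            raise ConfigurationError(f"multimapping genes not in host set: {unknown}")
        self._tags: dict[str, tuple[str, str, int]] = {}
        for g in self.host_genes:
            mapq = 0 if g in self.multimapping_genes else self.unique_mapq
            self._tags[_tag_for(g)] = ("host", g, mapq)
        for g in self.mito_genes:
            self._tags[_tag_for(g)] = ("mito", g, self.unique_mapq)
        for sp, cls in self.taxa.items():
            self._tags[_tag_for(sp)] = ("microbe", sp, 0)
        if len(self._tags) < len(self.host_genes) + len(self.mito_genes) + len(self.taxa):
            raise ConfigurationError("tag collision in toy reference")

    @property
    def all_genes(self) -> tuple[str, ...]:
        return tuple(self.host_genes) + tuple(self.mito_genes)

    def tag(self, name: str) -> str:
        """Tag sequence for a gene or species name."""
        return _tag_for(name)

    def lookup(self, seq: str) -> tuple[str, str, int] | None:
        """Resolve a read-2 sequence to ``(kind, name, mapq)`` or ``None``.

        ``kind`` is ``"host"``, ``"mito"`` or ``"microbe"``; only the first
        ``TAG_LENGTH`` bases are consulted.
        """
        return self._tags.get(seq[:TAG_LENGTH])

    def taxon_class(self, species: str) -> str:
        return self.taxa[species]
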