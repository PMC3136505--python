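"""Genetic codes and the single-nucleotide codon neighborhood.

The neutral expectation used throughout the package is built from the set of
ordered sense->sense codon pairs that differ at exactly one nucleotide
position.  Under the assumption of completely random amino acid replacement,
every nonsynonymous pair in this neighborhood is equally likely, so the
neighborhood fully determines the null distribution of property-change
magnitudes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

#: All 64 codons in lexicographic order.
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)

STOP = "*"


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino acid translation table.

    ``table`` maps each of the 64 codons to a one-letter amino acid or ``*``
    for stop.  The two codes relevant to mitochondrial protein-coding genes
    are bundled: the standard nuclear code and the vertebrate mitochondrial
    code (the default for this pipeline, since the analyzed genes are
    mtDNA-encoded).
    """

    name: str
    table: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64 or set(self.table) != set(ALL_CODONS):
            raise ValueError("genetic code must define all 64 codons")
        if STOP not in self.table.values():
            raise ValueError("genetic code must have a non-empty stop set")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.table[c] != STOP)

    def translate(self, codon: str) -> str:
        """Translate one codon; returns ``*`` for stops."""
        return self.table[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return self.table[codon.upper()] == STOP

    @classmethod
    def from_ncbi_id(cls, table_id: int, name: str | None = None) -> "GeneticCode":
        bio = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(bio.forward_table)
        for stop in bio.stop_codons:
            table[stop] = STOP
        return cls(name=name or bio.names[0], table=table)

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_ncbi_id(1, "standard")

    @classmethod
    def vertebrate_mitochondrial(cls) -> "GeneticCode":
        return cls.from_ncbi_id(2, "vertebrate_mitochondrial")


def get_code(name: str) -> GeneticCode:
    """Resolve a genetic code by configuration name."""
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    if key in {"standard", "nuclear", "1"}:
        return GeneticCode.standard()
    if key in {"vertebrate_mitochondrial", "mitochondrial", "mito", "2"}:
        return GeneticCode.vertebrate_mitochondrial()
    raise KeyError(f"unknown genetic code: {name!r}")


@dataclass(frozen=True)
class NeighborhoodPair:
    """One ordered sense->sense codon pair differing at a single position."""

    source_codon: str
    target_codon: str
    source_aa: str
    target_aa: str

    @property
    def synonymous(self) -> bool:
        return self.source_aa == self.target_aa


def codon_neighbors(codon: str) -> list[str]:
    """The 9 codons reachable from ``codon`` by one nucleotide change."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                out.append(codon[:pos] + nt + codon[pos + 1 :])
    return out


def build_neighborhood(
    code: GeneticCode, include_synonymous: bool = False
) -> list[NeighborhoodPair]:
    """Enumerate ordered single-nucleotide sense->sense codon pairs.

    By default only nonsynonymous pairs are returned, because only those
    enter the property-change statistics.  Order is lexicographic by source
    codon then target codon, so the result is deterministic.
    """
    pairs: list[NeighborhoodPair] = []
    for source in ALL_CODONS:
        if code.is_stop(source):
            continue
        src_aa = code.translate(source)
        for target in sorted(codon_neighbors(source)):
            if code.is_stop(target):
                continue
            tgt_aa = code.translate(target)
            if not include_synonymous and tgt_aa == src_aa:
                continue
            pairs.append(NeighborhoodPair(source, target, src_aa, tgt_aa))
    return pairs
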