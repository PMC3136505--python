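"""Readers and writers for the package's external representations.

FASTA codon alignments (Biopython), Newick trees (DendroPy), tab-separated
amino-acid property tables, taxon->group assignment files, and the TSV result
reports.  Every reader either returns an object satisfying its type
invariants or raises a typed error from :mod:`propsel.errors`; there are no
silent partial parses.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    CompletenessError,
    FrameError,
    LabelError,
    PropertyLookupError,
    PropertyValueError,
    TreeParseError,
)

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

_ALIGNMENT_ALPHABET = frozenset("ACGTN-")


@dataclass
class CodonAlignment:
    """An in-frame codon alignment: taxa x codon columns.

    Sequences are upper-case nucleotide strings of identical length divisible
    by 3.  Gaps ('-') and ambiguous bases ('N') are legal; any codon
    containing one is *masked* at that (taxon, site) and excluded downstream.
    Codon sites are cited 1-based in all reports; internal indices are
    0-based.
    """

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentShapeError("taxon/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise LabelError("duplicate taxon labels in alignment")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentShapeError(f"ragged sequence lengths: {sorted(lengths)}")
        length = lengths.pop() if lengths else 0
        if length % 3 != 0:
            raise FrameError(f"alignment length {length} not divisible by 3")
        bad = set("".join(self.sequences)) - _ALIGNMENT_ALPHABET
        if bad:
            raise AlphabetError(f"illegal characters in alignment: {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        """Number of codon columns."""
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def codon(self, taxon_index: int, site_index: int) -> str:
        """Codon of one taxon at one 0-based codon site."""
        return self.sequences[taxon_index][3 * site_index : 3 * site_index + 3]

    def is_masked(self, taxon_index: int, site_index: int) -> bool:
        """True when the codon contains a gap or an N."""
        return any(c in "N-" for c in self.codon(taxon_index, site_index))

    def column(self, site_index: int) -> dict[str, str | None]:
        """Taxon -> codon at a site, with masked codons mapped to None."""
        return {
            taxon: (None if self.is_masked(i, site_index) else self.codon(i, site_index))
            for i, taxon in enumerate(self.taxa)
        }

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        """Restrict to the given taxa, preserving the site frame."""
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise LabelError(f"taxa absent from alignment: {missing}")
        return CodonAlignment(
            taxa=list(taxa), sequences=[self.sequences[index[t]] for t in taxa]
        )


def read_codon_alignment(path: str | Path) -> CodonAlignment:
    """Read an in-frame FASTA codon alignment, preserving record order."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    return CodonAlignment(
        taxa=[r.id for r in records], sequences=[str(r.seq) for r in records]
    )


def write_codon_alignment(alignment: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in zip(alignment.taxa, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


class Phylogeny:
    """A rooted tree with uniquely labeled leaves.

    Thin wrapper over a :class:`dendropy.Tree` that gives every node a stable
    address (leaves keep their taxon labels, internal nodes are numbered in
    preorder) and exposes branches as (parent, child) label pairs.  Branch
    lengths are carried for simulation but ignored by the parsimony stage.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) < 2:
            raise TreeParseError("tree must have at least 2 leaves")
        if len(set(labels)) != len(labels):
            raise LabelError("duplicate leaf labels in tree")
        self._labels: dict[int, str] = {}
        n_internal = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                self._labels[id(node)] = node.taxon.label
            else:
                self._labels[id(node)] = f"node{n_internal}"
                n_internal += 1

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        from dendropy.dataio.newickreader import NewickReader

        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise LabelError(f"duplicate leaf labels in tree: {exc}") from exc
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeParseError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    def label(self, node: dendropy.Node) -> str:
        return self._labels[id(node)]

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def postorder(self):
        return self._tree.postorder_node_iter()

    def preorder(self):
        return self._tree.preorder_node_iter()

    def branches(self) -> list[tuple[str, str, float | None]]:
        """(parent label, child label, branch length) in preorder."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                out.append(
                    (self.label(node.parent_node), self.label(node), node.edge.length)
                )
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf sets of all internal edges; topology fingerprint for tests."""
        out: set[frozenset[str]] = set()
        for node in self._tree.postorder_node_iter():
            if node.parent_node is not None:
                out.add(
                    frozenset(l.taxon.label for l in node.leaf_iter())
                )
        return out

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_tree(path: str | Path) -> Phylogeny:
    """Read a single rooted Newick tree."""
    text = Path(path).read_text().strip()
    if not text:
        raise TreeParseError(f"empty tree file: {path}")
    return Phylogeny.from_newick(text)


def write_tree(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


@dataclass
class PropertyTable:
    """Named physicochemical properties, each valued on the 20 amino acids.

    ``values[name][aa]`` is the property value; ``descriptions`` optionally
    carries a human-readable definition per property.  The bundled default
    table (see :func:`load_default_properties`) holds the 20 properties used
    throughout the pipeline; it is configuration, not code, so alternative
    value sets can be substituted from any TSV with the same layout.
    """

    values: dict[str, dict[str, float]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values:
            raise CompletenessError("property table has no properties")
        for name, row in self.values.items():
            missing = [aa for aa in AMINO_ACIDS if aa not in row]
            if missing:
                raise CompletenessError(
                    f"property {name!r} missing amino acids: {missing}"
                )

    @property
    def properties(self) -> list[str]:
        return list(self.values)

    def value(self, prop: str, aa: str) -> float:
        try:
            row = self.values[prop]
        except KeyError as exc:
            raise PropertyLookupError(f"unknown property {prop!r}") from exc
        try:
            return row[aa]
        except KeyError as exc:
            raise PropertyLookupError(f"nonstandard amino acid {aa!r}") from exc

    def delta(self, prop: str, from_aa: str, to_aa: str) -> float:
        """Signed property change of a replacement from_aa -> to_aa."""
        return self.value(prop, to_aa) - self.value(prop, from_aa)

    def subset(self, names: list[str]) -> "PropertyTable":
        unknown = [n for n in names if n not in self.values]
        if unknown:
            raise PropertyLookupError(f"unknown properties: {unknown}")
        return PropertyTable(
            values={n: dict(self.values[n]) for n in names},
            descriptions={n: self.descriptions.get(n, "") for n in names},
        )


def read_property_table(path: str | Path) -> PropertyTable:
    """Read a TSV property table.

    Layout: header ``property<TAB>[description<TAB>]A<TAB>C...`` with one row
    per property.  Extra non-amino-acid columns besides ``description`` are
    rejected; every row must value all 20 amino acids numerically.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "property" not in df.columns:
        raise CompletenessError("property table needs a 'property' column")
    extra = [
        c for c in df.columns if c not in ("property", "description") and c not in AMINO_ACIDS
    ]
    if extra:
        raise CompletenessError(f"unexpected columns in property table: {extra}")
    missing = [aa for aa in AMINO_ACIDS if aa not in df.columns]
    if missing:
        raise CompletenessError(f"property table missing amino-acid columns: {missing}")
    if df["property"].duplicated().any():
        raise LabelError("duplicate property names in table")
    values: dict[str, dict[str, float]] = {}
    descriptions: dict[str, str] = {}
    for _, row in df.iterrows():
        name = row["property"]
        vals: dict[str, float] = {}
        for aa in AMINO_ACIDS:
            cell = row[aa]
            try:
                vals[aa] = float(cell)
            except (TypeError, ValueError) as exc:
                raise PropertyValueError(
                    f"non-numeric value {cell!r} for property {name!r}, amino acid {aa}"
                ) from exc
        values[name] = vals
        if "description" in df.columns and isinstance(row.get("description"), str):
            descriptions[name] = row["description"]
    return PropertyTable(values=values, descriptions=descriptions)


def write_property_table(table: PropertyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("property\tdescription\t" + "\t".join(AMINO_ACIDS) + "\n")
        for name, row in table.values.items():
            desc = table.descriptions.get(name, "")
            cells = "\t".join(repr(row[aa]) for aa in AMINO_ACIDS)
            fh.write(f"{name}\t{desc}\t{cells}\n")


def load_default_properties() -> PropertyTable:
    """Load the bundled 20-property table."""
    ref = importlib.resources.files("propsel") / "data" / "aa_properties.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_property_table(path)


@dataclass
class GroupDefinition:
    """Assignment of taxa to named clade groups (e.g. A / L / C)."""

    groups: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, taxa in self.groups.items():
            if not taxa:
                raise LabelError(f"group {name!r} is empty")
            for taxon in taxa:
                if taxon in seen:
                    raise LabelError(
                        f"taxon {taxon!r} assigned to both {seen[taxon]!r} and {name!r}"
                    )
                seen[taxon] = name

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    def taxa(self, group: str) -> frozenset[str]:
        return self.groups[group]


def read_groups(path: str | Path) -> GroupDefinition:
    """Read a two-column TSV ``taxon<TAB>group``."""
    groups: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower() == "taxon\tgroup":
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LabelError(f"{path}:{lineno}: expected 'taxon<TAB>group'")
        taxon, group = parts
        groups.setdefault(group, set()).add(taxon)
    return GroupDefinition(groups={g: frozenset(t) for g, t in groups.items()})


def write_groups(groups: GroupDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tgroup\n")
        for name, taxa in groups.groups.items():
            for taxon in sorted(taxa):
                fh.write(f"{taxon}\t{name}\n")
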