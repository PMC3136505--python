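"""Codon-alignment simulation with known ground truth.

Sequences evolve along a rooted tree with branch lengths in expected
substitutions per codon site.  Substitution is a continuous-time jump
process per (branch, site): single-nucleotide changes are proposed uniformly
over the 9 codon neighbors, changes creating a stop codon are rejected, and
all other changes are accepted at a baseline rate.  Rates are normalized so
that one unit of branch length produces one expected substitution per site
under neutrality at stationarity (the stationary law of the neutral chain is
uniform over sense codons, and the root sequence is drawn from it, so the
realized distribution of nonsynonymous changes matches the neighborhood null
of :mod:`propsel.property_model` exactly — the keystone consistency between
simulator and analysis).

Destabilizing-selection bias: at chosen (clade, site) pairs the rate of any
nonsynonymous change falling in radical magnitude categories (6-8 by
default) of a chosen property is multiplied by beta >= 1.  beta = 1 is
exactly neutral.

Determinism: one master seed; each branch draws from its own substream keyed
by the child node label, so adding taxa does not perturb the substitutions
simulated on other branches.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, FrameError
from .genetic_code import GeneticCode, build_neighborhood, codon_neighbors
from .io import CodonAlignment, Phylogeny, PropertyTable, write_codon_alignment, write_tree
from .property_model import DESTABILIZING_CATEGORIES, NullModel
from .selection import SelectionCall


@dataclass(frozen=True)
class BiasSpec:
    """Destabilizing-selection bias planted at (clade, site) pairs."""

    clade: frozenset[str]
    sites: frozenset[int]  # 1-based codon sites
    property_name: str
    beta: float
    categories: tuple[int, ...] = DESTABILIZING_CATEGORIES


@dataclass
class SimulationSpec:
    """Everything needed to reproduce one simulated alignment."""

    tree: Phylogeny
    n_sites: int
    seed: int
    rate: float = 1.0
    code: GeneticCode = field(default_factory=GeneticCode.vertebrate_mitochondrial)
    table: PropertyTable | None = None
    bias: BiasSpec | None = None
    root_sequence: list[str] | None = None

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.rate < 0:
            raise ConfigError("rate must be >= 0")
        for _, _, length in self.tree.branches():
            if length is not None and length < 0:
                raise ConfigError("branch lengths must be >= 0")
        if self.bias is not None:
            if self.bias.beta < 1:
                raise ConfigError("bias strength beta must be >= 1")
            if self.table is None:
                raise ConfigError("bias requires a property table")
            if self.bias.property_name not in self.table.values:
                raise ConfigError(f"unknown bias property {self.bias.property_name!r}")
            bad = [s for s in self.bias.sites if not 1 <= s <= self.n_sites]
            if bad:
                raise ConfigError(f"bias sites outside 1..{self.n_sites}: {sorted(bad)}")
            leaves = set(self.tree.leaf_labels)
            unknown = self.bias.clade - leaves
            if unknown:
                raise ConfigError(f"bias clade taxa not in tree: {sorted(unknown)}")
        if self.root_sequence is not None and len(self.root_sequence) != self.n_sites:
            raise ConfigError("root sequence length must equal n_sites")


@dataclass(frozen=True)
class SimEvent:
    """One realized substitution, in simulation order."""

    site: int  # 1-based
    parent: str
    child: str
    from_codon: str
    to_codon: str


@dataclass
class SimulationTruth:
    """Ground truth of one simulation run."""

    spec: SimulationSpec
    root_sequence: list[str]
    events: list[SimEvent]
    leaf_sequences: dict[str, str]

    @property
    def planted_sites(self) -> frozenset[int]:
        return self.spec.bias.sites if self.spec.bias is not None else frozenset()

    def nonsynonymous_events(self) -> list[SimEvent]:
        code = self.spec.code
        return [
            e
            for e in self.events
            if code.translate(e.from_codon) != code.translate(e.to_codon)
        ]

    def replay(self) -> dict[str, str]:
        """Re-derive leaf sequences from the root and the event log."""
        tree = self.spec.tree
        by_branch: dict[tuple[str, str], list[SimEvent]] = {}
        for e in self.events:
            by_branch.setdefault((e.parent, e.child), []).append(e)
        seqs: dict[str, list[str]] = {tree.label(tree.root): list(self.root_sequence)}
        for node in tree.preorder():
            if node.parent_node is None:
                continue
            parent = tree.label(node.parent_node)
            child = tree.label(node)
            seq = list(seqs[parent])
            for e in by_branch.get((parent, child), []):
                if seq[e.site - 1] != e.from_codon:
                    raise FrameError(
                        f"event log inconsistent at site {e.site} on {parent}->{child}"
                    )
                seq[e.site - 1] = e.to_codon
            seqs[child] = seq
        return {
            label: "".join(seqs[label]) for label in tree.leaf_labels
        }


def _branch_rng(seed: int, child_label: str) -> np.random.Generator:
    digest = hashlib.sha256(child_label.encode()).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:4], "big")])


class _RateTables:
    """Per-codon substitution targets and rates, neutral and biased."""

    def __init__(self, spec: SimulationSpec):
        code = spec.code
        sense = list(code.sense_codons)
        # normalization: mean neutral exit weight over sense codons -> rate 1
        neutral_targets: dict[str, list[str]] = {}
        for c in sense:
            neutral_targets[c] = [t for t in codon_neighbors(c) if not code.is_stop(t)]
        z_norm = sum(len(t) for t in neutral_targets.values()) / len(sense)

        radical: set[tuple[str, str]] = set()
        if spec.bias is not None:
            null = NullModel.build(
                spec.table.subset([spec.bias.property_name]), build_neighborhood(code)
            )
            for c in sense:
                aa_c = code.translate(c)
                for t in neutral_targets[c]:
                    aa_t = code.translate(t)
                    if aa_t == aa_c:
                        continue
                    cat = null.categorize(spec.bias.property_name, aa_c, aa_t)
                    if cat in spec.bias.categories:
                        radical.add((c, t))

        self.targets = neutral_targets
        self.neutral_rate = {c: len(neutral_targets[c]) / z_norm for c in sense}
        self.neutral_probs = {
            c: np.full(len(neutral_targets[c]), 1.0 / len(neutral_targets[c]))
            for c in sense
        }
        if spec.bias is not None:
            beta = spec.bias.beta
            self.biased_rate = {}
            self.biased_probs = {}
            for c in sense:
                w = np.array(
                    [beta if (c, t) in radical else 1.0 for t in neutral_targets[c]]
                )
                self.biased_rate[c] = w.sum() / z_norm
                self.biased_probs[c] = w / w.sum()
        else:
            self.biased_rate = self.neutral_rate
            self.biased_probs = self.neutral_probs


def simulate(spec: SimulationSpec) -> tuple[CodonAlignment, Phylogeny, SimulationTruth]:
    """Evolve a codon alignment along the spec's tree.

    Returns the leaf alignment (taxa in tree leaf order), the tree, and the
    full ground truth (root sequence plus every realized substitution).
    Identical specs (including seed) give identical output.
    """
    spec.validate()
    tree = spec.tree
    code = spec.code
    tables = _RateTables(spec)
    sense = list(code.sense_codons)

    root_rng = _branch_rng(spec.seed, "@root")
    if spec.root_sequence is not None:
        root_seq = list(spec.root_sequence)
        bad = [c for c in root_seq if code.is_stop(c)]
        if bad:
            raise ConfigError(f"stop codons in root sequence: {bad}")
    else:
        root_seq = [sense[i] for i in root_rng.integers(0, len(sense), spec.n_sites)]

    biased_leafsets: set[str] = set()
    if spec.bias is not None:
        for node in tree.preorder():
            leaves = {l.taxon.label for l in node.leaf_iter()}
            if leaves <= spec.bias.clade:
                biased_leafsets.add(tree.label(node))
    biased_sites = (
        {s - 1 for s in spec.bias.sites} if spec.bias is not None else set()
    )

    events: list[SimEvent] = []
    seqs: dict[str, list[str]] = {tree.label(tree.root): root_seq}
    for node in tree.preorder():
        if node.parent_node is None:
            continue
        parent = tree.label(node.parent_node)
        child = tree.label(node)
        length = (node.edge.length or 0.0) * spec.rate
        rng = _branch_rng(spec.seed, child)
        seq = list(seqs[parent])
        branch_biased = child in biased_leafsets
        for site in range(spec.n_sites):
            if length == 0.0:
                break
            site_biased = branch_biased and site in biased_sites
            rate_of = tables.biased_rate if site_biased else tables.neutral_rate
            probs_of = tables.biased_probs if site_biased else tables.neutral_probs
            t = 0.0
            codon = seq[site]
            while True:
                lam = rate_of[codon]
                t += rng.exponential(1.0 / lam)
                if t > length:
                    break
                target = tables.targets[codon][
                    rng.choice(len(tables.targets[codon]), p=probs_of[codon])
                ]
                events.append(
                    SimEvent(
                        site=site + 1,
                        parent=parent,
                        child=child,
                        from_codon=codon,
                        to_codon=target,
                    )
                )
                codon = target
            seq[site] = codon
        seqs[child] = seq

    leaf_seqs = {label: "".join(seqs[label]) for label in tree.leaf_labels}
    alignment = CodonAlignment(
        taxa=list(tree.leaf_labels), sequences=[leaf_seqs[t] for t in tree.leaf_labels]
    )
    truth = SimulationTruth(
        spec=spec, root_sequence=root_seq, events=events, leaf_sequences=leaf_seqs
    )
    return alignment, tree, truth


@dataclass(frozen=True)
class ConfusionSummary:
    """Planted-site recovery of one analysis run."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else 1.0


def truth_report(
    truth: SimulationTruth,
    calls: list[SelectionCall],
    property_name: str | None = None,
) -> ConfusionSummary:
    """Compare positive-destabilizing calls against the planted sites.

    A site counts as called when it carries at least one positive call in a
    destabilizing category (optionally restricted to one property).  Sites
    are the simulation's own 1-based codon sites; calls outside that frame
    raise a frame error.
    """
    n_sites = truth.spec.n_sites
    called: set[int] = set()
    for call in calls:
        if call.site < 1 or call.site > n_sites:
            raise FrameError(f"call site {call.site} outside simulated frame 1..{n_sites}")
        if call.direction != "positive" or call.regime != "destabilizing":
            continue
        if property_name is not None and call.property_name != property_name:
            continue
        called.add(call.site)
    planted = set(truth.planted_sites)
    tp = len(called & planted)
    fp = len(called - planted)
    fn = len(planted - called)
    tn = n_sites - tp - fp - fn
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


def write_run(
    outdir: str | Path,
    alignment: CodonAlignment,
    tree: Phylogeny,
    truth: SimulationTruth,
) -> None:
    """Write FASTA + Newick + truth TSV + spec echo for full reproducibility."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_codon_alignment(alignment, outdir / "alignment.fasta")
    write_tree(tree, outdir / "tree.nwk")
    with open(outdir / "truth_events.tsv", "w") as fh:
        fh.write("site\tparent\tchild\tfrom_codon\tto_codon\n")
        for e in truth.events:
            fh.write(f"{e.site}\t{e.parent}\t{e.child}\t{e.from_codon}\t{e.to_codon}\n")
    spec = truth.spec
    with open(outdir / "spec.txt", "w") as fh:
        fh.write(f"n_sites\t{spec.n_sites}\n")
        fh.write(f"seed\t{spec.seed}\n")
        fh.write(f"rate\t{spec.rate}\n")
        fh.write(f"genetic_code\t{spec.code.name}\n")
        fh.write(f"root_sequence\t{''.join(truth.root_sequence)}\n")
        if spec.bias is not None:
            fh.write(f"bias_property\t{spec.bias.property_name}\n")
            fh.write(f"bias_beta\t{spec.bias.beta}\n")
            fh.write(f"bias_sites\t{','.join(map(str, sorted(spec.bias.sites)))}\n")
            fh.write(f"bias_clade\t{','.join(sorted(spec.bias.clade))}\n")
            fh.write(f"bias_categories\t{','.join(map(str, spec.bias.categories))}\n")
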