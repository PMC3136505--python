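"""Parsimony ancestral reconstruction and replacement-event enumeration.

Ancestral codon states are assigned per site by Fitch parsimony generalized
to multifurcating nodes (Hartigan's algorithm), which minimizes the number of
codon state changes on the rooted tree.  Reconstruction is on codon states
rather than amino acids so that synonymous changes remain identifiable and
can be excluded from the property statistics.

Determinism: on the top-down pass the parent's state is kept whenever it is
optimal for the child; otherwise the lexicographically smallest codon in the
child's optimal set is chosen.  A codon change touching several nucleotide
positions on one branch is counted as a single amino-acid replacement.
Masked (gap/N) leaf codons are wildcards, the standard missing-data
treatment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import LabelError
from .genetic_code import GeneticCode
from .io import CodonAlignment, Phylogeny

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplacementEvent:
    """One inferred codon change on one branch at one codon site."""

    site: int  # 1-based codon site
    parent: str
    child: str
    from_codon: str
    to_codon: str
    from_aa: str
    to_aa: str

    @property
    def synonymous(self) -> bool:
        return self.from_aa == self.to_aa


@dataclass
class AncestralStates:
    """Per-site parsimony assignments and minimum change counts.

    ``states[site][node_label]`` is the assigned codon; sites with fewer than
    2 unmasked taxa are skipped (absent from ``states``/``changes`` and
    listed in ``skipped_sites``).  All site keys are 0-based internally.
    """

    states: dict[int, dict[str, str]]
    changes: dict[int, int]
    skipped_sites: list[int] = field(default_factory=list)

    @property
    def total_changes(self) -> int:
        return sum(self.changes.values())


def fitch_reconstruct(alignment: CodonAlignment, tree: Phylogeny) -> AncestralStates:
    """Minimum-change codon assignment for every site and node.

    Raises :class:`LabelError` if the tree's leaves are not all present in
    the alignment.
    """
    taxon_index = {t: i for i, t in enumerate(alignment.taxa)}
    missing = [l for l in tree.leaf_labels if l not in taxon_index]
    if missing:
        raise LabelError(f"tree leaves absent from alignment: {missing}")

    postorder = list(tree.postorder())
    preorder = list(tree.preorder())
    states: dict[int, dict[str, str]] = {}
    changes: dict[int, int] = {}
    skipped: list[int] = []

    for site in range(alignment.n_sites):
        leaf_codon: dict[str, str | None] = {}
        for label in tree.leaf_labels:
            i = taxon_index[label]
            leaf_codon[label] = None if alignment.is_masked(i, site) else alignment.codon(i, site)
        n_unmasked = sum(c is not None for c in leaf_codon.values())
        if n_unmasked < 2:
            skipped.append(site)
            logger.info("site %d skipped: fewer than 2 unmasked taxa", site + 1)
            continue

        # Bottom-up (Hartigan): per node, the set of states attaining the
        # per-subtree minimum, plus the accumulated minimum change count.
        opt_set: dict[int, frozenset[str] | None] = {}  # None = wildcard
        cost = 0
        for node in postorder:
            if node.is_leaf():
                codon = leaf_codon[tree.label(node)]
                opt_set[id(node)] = None if codon is None else frozenset([codon])
                continue
            child_sets = [
                opt_set[id(ch)] for ch in node.child_nodes() if opt_set[id(ch)] is not None
            ]
            if not child_sets:
                opt_set[id(node)] = None
                continue
            tally: dict[str, int] = {}
            for cs in child_sets:
                for state in cs:
                    tally[state] = tally.get(state, 0) + 1
            k_max = max(tally.values())
            opt_set[id(node)] = frozenset(s for s, k in tally.items() if k == k_max)
            cost += len(child_sets) - k_max

        # Top-down: keep the parent's state when optimal, else smallest codon.
        assignment: dict[str, str] = {}
        node_state: dict[int, str] = {}
        for node in preorder:
            s = opt_set[id(node)]
            if s is None:
                # fully-masked subtree: no data, no assignment, no events
                continue
            if node.parent_node is None:
                chosen = min(s)
            else:
                parent_state = node_state.get(id(node.parent_node))
                chosen = parent_state if parent_state in s else min(s)
            node_state[id(node)] = chosen
            assignment[tree.label(node)] = chosen

        states[site] = assignment
        changes[site] = cost

    return AncestralStates(states=states, changes=changes, skipped_sites=skipped)


def enumerate_replacements(
    states: AncestralStates, tree: Phylogeny, code: GeneticCode
) -> list[ReplacementEvent]:
    """All branch-site codon changes implied by a reconstruction.

    One event per (branch, site) where parent and child assignments differ,
    ordered by site then preorder branch position.  Synonymous events carry
    the flag and are excluded from property statistics downstream.
    """
    branch_order = [(p, c) for p, c, _ in tree.branches()]
    events: list[ReplacementEvent] = []
    for site in sorted(states.states):
        assignment = states.states[site]
        for parent, child in branch_order:
            if parent not in assignment or child not in assignment:
                continue
            src, tgt = assignment[parent], assignment[child]
            if src != tgt:
                events.append(
                    ReplacementEvent(
                        site=site + 1,
                        parent=parent,
                        child=child,
                        from_codon=src,
                        to_codon=tgt,
                        from_aa=code.translate(src),
                        to_aa=code.translate(tgt),
                    )
                )
    return events


def write_events_tsv(events: list[ReplacementEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tparent\tchild\tfrom_codon\tto_codon\tfrom_aa\tto_aa\tsynonymous\n")
        for e in events:
            fh.write(
                f"{e.site}\t{e.parent}\t{e.child}\t{e.from_codon}\t{e.to_codon}"
                f"\t{e.from_aa}\t{e.to_aa}\t{int(e.synonymous)}\n"
            )
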