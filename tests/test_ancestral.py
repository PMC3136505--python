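"""Parsimony reconstruction checked against exhaustive minimization.

The oracle enumerates every assignment of observed states to internal nodes
(an optimal uniform-cost parsimony labeling always exists within the
observed state set) and takes the true minimum change count.
"""

import itertools

import numpy as np
import pytest

import propsel as ps
from propsel.errors import LabelError


def exhaustive_min_changes(tree: ps.Phylogeny, leaf_states: dict[str, str]) -> int:
    internals = [n for n in tree.preorder() if not n.is_leaf()]
    states = sorted(set(leaf_states.values()))
    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        for leaf in tree.preorder():
            if leaf.is_leaf():
                assign[id(leaf)] = leaf_states[tree.label(leaf)]
        cost = 0
        for node in tree.preorder():
            if node.parent_node is not None:
                cost += assign[id(node)] != assign[id(node.parent_node)]
        best = cost if best is None else min(best, cost)
    return best


def alignment_from_states(tree, leaf_states):
    return ps.CodonAlignment(
        taxa=list(leaf_states), sequences=[leaf_states[t] for t in leaf_states]
    )


def random_binary_newick(labels, rng):
    nodes = [f"{l}:0.1" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):0.1")
    return nodes[0] + ";"


class TestFitch:
    def test_uniform_site_has_no_changes(self, quartet_tree):
        aln = alignment_from_states(
            quartet_tree, {t: "ATG" for t in "abcd"}
        )
        states = ps.fitch_reconstruct(aln, quartet_tree)
        assert states.changes[0] == 0
        assert set(states.states[0].values()) == {"ATG"}

    def test_congruent_split_needs_one_change(self, quartet_tree):
        aln = alignment_from_states(
            quartet_tree, {"a": "ATG", "b": "ATG", "c": "ACG", "d": "ACG"}
        )
        states = ps.fitch_reconstruct(aln, quartet_tree)
        assert states.changes[0] == 1

    def test_incongruent_split_needs_two_changes(self):
        tree = ps.Phylogeny.from_newick("((a,c),(b,d));")
        aln = alignment_from_states(
            tree, {"a": "ATG", "c": "ACG", "b": "ATG", "d": "ACG"}
        )
        states = ps.fitch_reconstruct(aln, tree)
        assert states.changes[0] == 2

    def test_matches_exhaustive_minimum_on_random_instances(self):
        rng = np.random.default_rng(7)
        codons = ["ATG", "ACG", "AAG", "ATA"]
        for _ in range(60):
            n_leaves = int(rng.integers(4, 7))
            labels = [f"t{i}" for i in range(n_leaves)]
            tree = ps.Phylogeny.from_newick(random_binary_newick(labels, rng))
            leaf_states = {l: codons[rng.integers(0, len(codons))] for l in labels}
            aln = alignment_from_states(tree, leaf_states)
            got = ps.fitch_reconstruct(aln, tree).changes[0]
            want = exhaustive_min_changes(tree, leaf_states)
            assert got == want, (tree.to_newick(), leaf_states)

    def test_multifurcating_tree_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(11)
        tree = ps.Phylogeny.from_newick("(a,b,c,d,e);")
        codons = ["ATG", "ACG", "AAG"]
        for _ in range(30):
            leaf_states = {l: codons[rng.integers(0, 3)] for l in "abcde"}
            aln = alignment_from_states(tree, leaf_states)
            got = ps.fitch_reconstruct(aln, tree).changes[0]
            assert got == exhaustive_min_changes(tree, leaf_states)

    def test_masked_leaf_is_wildcard(self, quartet_tree):
        aln = alignment_from_states(
            quartet_tree, {"a": "ATG", "b": "NNN", "c": "ATG", "d": "ATG"}
        )
        states = ps.fitch_reconstruct(aln, quartet_tree)
        assert states.changes[0] == 0
        assert "b" not in states.states[0]  # masked leaf carries no state

    def test_site_with_single_unmasked_taxon_skipped(self, quartet_tree):
        aln = alignment_from_states(
            quartet_tree, {"a": "ATG", "b": "---", "c": "---", "d": "---"}
        )
        states = ps.fitch_reconstruct(aln, quartet_tree)
        assert states.skipped_sites == [0]
        assert 0 not in states.states

    def test_label_mismatch_raises(self, quartet_tree):
        aln = alignment_from_states(quartet_tree, {"a": "ATG", "b": "ATG"})
        with pytest.raises(LabelError):
            ps.fitch_reconstruct(aln, quartet_tree)

    def test_taxon_order_does_not_change_events(self, quartet_tree, mito_code):
        leaf_states = {"a": "ATG", "b": "ACG", "c": "ATG", "d": "AAG"}
        aln1 = alignment_from_states(quartet_tree, leaf_states)
        shuffled = {k: leaf_states[k] for k in ["d", "b", "a", "c"]}
        aln2 = alignment_from_states(quartet_tree, shuffled)
        ev1 = ps.enumerate_replacements(
            ps.fitch_reconstruct(aln1, quartet_tree), quartet_tree, mito_code
        )
        ev2 = ps.enumerate_replacements(
            ps.fitch_reconstruct(aln2, quartet_tree), quartet_tree, mito_code
        )
        assert ev1 == ev2


class TestEnumerate:
    def test_no_changes_yields_no_events(self, quartet_tree, mito_code):
        aln = alignment_from_states(quartet_tree, {t: "ATG" for t in "abcd"})
        states = ps.fitch_reconstruct(aln, quartet_tree)
        assert ps.enumerate_replacements(states, quartet_tree, mito_code) == []

    def test_single_replacement_translated(self, quartet_tree, mito_code):
        aln = alignment_from_states(
            quartet_tree, {"a": "ATG", "b": "ATG", "c": "ATG", "d": "ACG"}
        )
        states = ps.fitch_reconstruct(aln, quartet_tree)
        events = ps.enumerate_replacements(states, quartet_tree, mito_code)
        assert len(events) == 1
        e = events[0]
        assert (e.from_codon, e.to_codon) == ("ATG", "ACG")
        assert (e.from_aa, e.to_aa) == ("M", "T")
        assert not e.synonymous
        assert e.site == 1

    def test_event_count_equals_fitch_minimum_per_site(self, mito_code):
        rng = np.random.default_rng(3)
        tree = ps.Phylogeny.from_newick(
            random_binary_newick([f"t{i}" for i in range(6)], rng)
        )
        sense = list(mito_code.sense_codons)
        seqs = {
            tree.leaf_labels[i]: "".join(
                sense[k] for k in rng.integers(0, len(sense), 30)
            )
            for i in range(6)
        }
        aln = alignment_from_states(tree, seqs)
        states = ps.fitch_reconstruct(aln, tree)
        events = ps.enumerate_replacements(states, tree, mito_code)
        per_site = {}
        for e in events:
            per_site[e.site - 1] = per_site.get(e.site - 1, 0) + 1
        for site, minimum in states.changes.items():
            assert per_site.get(site, 0) == minimum

    def test_synonymous_events_flagged(self, quartet_tree, mito_code):
        # CTA -> CTG is synonymous (both leucine)
        aln = alignment_from_states(
            quartet_tree, {"a": "CTA", "b": "CTA", "c": "CTA", "d": "CTG"}
        )
        states = ps.fitch_reconstruct(aln, quartet_tree)
        events = ps.enumerate_replacements(states, quartet_tree, mito_code)
        assert len(events) == 1 and events[0].synonymous
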