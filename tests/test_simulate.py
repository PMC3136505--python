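import numpy as np
import pytest

import propsel as ps
from propsel.errors import ConfigError


def spec_for(newick, n_sites=50, seed=0, table=None, bias=None):
    return ps.SimulationSpec(
        tree=ps.Phylogeny.from_newick(newick),
        n_sites=n_sites,
        seed=seed,
        table=table,
        bias=bias,
    )


class TestSimulate:
    def test_zero_branch_lengths_copy_root(self):
        spec = spec_for("(a:0.0,b:0.0);", n_sites=30)
        aln, tree, truth = ps.simulate(spec)
        assert truth.events == []
        assert aln.sequences[0] == aln.sequences[1] == "".join(truth.root_sequence)

    def test_identical_seeds_identical_output(self, tmp_path, star8_newick):
        runs = []
        for _ in range(2):
            aln, tree, truth = ps.simulate(spec_for(star8_newick, 80, seed=11))
            out = tmp_path / f"r{len(runs)}.fasta"
            ps.write_codon_alignment(aln, out)
            runs.append(out.read_bytes())
        assert runs[0] == runs[1]

    def test_different_seeds_differ(self, star8_newick):
        a1, _, _ = ps.simulate(spec_for(star8_newick, 80, seed=1))
        a2, _, _ = ps.simulate(spec_for(star8_newick, 80, seed=2))
        assert a1.sequences != a2.sequences

    def test_event_log_replays_to_leaves(self, star8_newick):
        _, _, truth = ps.simulate(spec_for(star8_newick, 100, seed=5))
        assert truth.replay() == truth.leaf_sequences

    def test_no_stop_codons_in_leaves(self, star8_newick):
        aln, _, truth = ps.simulate(spec_for(star8_newick, 100, seed=6))
        code = truth.spec.code
        for seq in aln.sequences:
            for i in range(0, len(seq), 3):
                assert not code.is_stop(seq[i : i + 3])

    def test_substitution_count_matches_poisson_moments(self):
        """Rates are normalized to one expected substitution per site per
        unit branch length at neutrality; the realized total over replicates
        must match that Poisson mean within 3 standard errors."""
        newick = "(a:0.2,b:0.2);"
        n_sites, n_reps = 400, 30
        lam = 0.4 * n_sites  # total tree length x sites
        counts = [
            len(ps.simulate(spec_for(newick, n_sites, seed=s))[2].events)
            for s in range(n_reps)
        ]
        se = np.sqrt(lam / n_reps)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_branch_substreams_stable_under_added_taxa(self):
        """Adding a taxon must not perturb substitutions on other branches."""
        a1, _, t1 = ps.simulate(spec_for("(a:0.2,b:0.2);", 60, seed=9))
        a2, _, t2 = ps.simulate(spec_for("(a:0.2,b:0.2,c:0.2);", 60, seed=9))
        ev1 = [e for e in t1.events if e.child == "a"]
        ev2 = [e for e in t2.events if e.child == "a"]
        assert ev1 == ev2

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_sites": 0},
            {"rate": -1.0},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        tree = ps.Phylogeny.from_newick("(a:0.1,b:0.1);")
        spec = ps.SimulationSpec(tree=tree, seed=0, **{"n_sites": 10, **kwargs})
        with pytest.raises(ConfigError):
            spec.validate()

    def test_bias_requires_table_and_valid_sites(self):
        tree = ps.Phylogeny.from_newick("(a:0.1,b:0.1);")
        bias = ps.BiasSpec(
            clade=frozenset("ab"), sites=frozenset({99}), property_name="P", beta=10.0
        )
        spec = ps.SimulationSpec(tree=tree, n_sites=10, seed=0, bias=bias)
        with pytest.raises(ConfigError):
            spec.validate()
        spec2 = ps.SimulationSpec(
            tree=tree,
            n_sites=10,
            seed=0,
            table=ps.load_default_properties(),
            bias=bias,
        )
        with pytest.raises(ConfigError):  # site 99 outside 1..10
            spec2.validate()


class TestNeutralLaw:
    def test_neutral_categories_match_expected_distribution(
        self, default_table, null_model
    ):
        """Keystone consistency: the neutral simulator's event law equals the
        neighborhood null.  Tested on sites with exactly one event so the
        draws are independent, as a chi-square test requires."""
        from collections import Counter
        from scipy import stats as sps

        spec = spec_for("(a:0.02,b:0.02);", n_sites=120000, seed=0, table=default_table)
        _, _, truth = ps.simulate(spec)
        code = spec.code
        per_site = Counter(e.site for e in truth.events)
        solo = [
            e
            for e in truth.events
            if per_site[e.site] == 1
            and code.translate(e.from_codon) != code.translate(e.to_codon)
        ]
        assert len(solo) > 2500
        for prop in ("P", "H", "pK'"):
            observed = np.zeros(8)
            for e in solo:
                cat = null_model.categorize(
                    prop, code.translate(e.from_codon), code.translate(e.to_codon)
                )
                observed[cat - 1] += 1
            p = null_model.expecteds[prop]
            mask = p > 0
            chi2 = (
                (observed[mask] - len(solo) * p[mask]) ** 2 / (len(solo) * p[mask])
            ).sum()
            assert sps.chi2.sf(chi2, mask.sum() - 1) > 0.01

    def test_bias_enriches_radical_fraction(self, default_table, null_model):
        """beta = 10 at target sites must push the realized category 6-8
        fraction of the target property well above the neutral expectation."""
        newick = "(a:0.3,b:0.3,c:0.3,d:0.3);"
        planted = frozenset(range(1, 51))
        bias = ps.BiasSpec(
            clade=frozenset("abcd"), sites=planted, property_name="P", beta=10.0
        )
        spec = spec_for(newick, n_sites=200, seed=4, table=default_table, bias=bias)
        _, _, truth = ps.simulate(spec)
        code = spec.code

        def radical_fraction(events):
            cats = [
                null_model.categorize(
                    "P", code.translate(e.from_codon), code.translate(e.to_codon)
                )
                for e in events
            ]
            return np.mean([c >= 6 for c in cats])

        ns = truth.nonsynonymous_events()
        target = [e for e in ns if e.site in planted]
        rest = [e for e in ns if e.site not in planted]
        p_band = null_model.expecteds["P"][5:].sum()
        assert radical_fraction(target) > 2 * p_band
        assert radical_fraction(rest) < 2 * p_band


class TestTruthReport:
    def _truth(self, planted, n_sites=20):
        tree = ps.Phylogeny.from_newick("(a:0.1,b:0.1);")
        bias = ps.BiasSpec(
            clade=frozenset("ab"),
            sites=frozenset(planted),
            property_name="P",
            beta=10.0,
        )
        spec = ps.SimulationSpec(
            tree=tree,
            n_sites=n_sites,
            seed=0,
            table=ps.load_default_properties(),
            bias=bias,
        )
        return ps.SimulationTruth(
            spec=spec, root_sequence=["ATG"] * n_sites, events=[], leaf_sequences={}
        )

    def _call(self, site):
        return ps.SelectionCall(
            site=site,
            property_name="P",
            category=7,
            direction="positive",
            regime="destabilizing",
            z=4.0,
        )

    def test_perfect_recovery(self):
        truth = self._truth({3, 7})
        conf = ps.truth_report(truth, [self._call(3), self._call(7)])
        assert conf.sensitivity == 1.0 and conf.specificity == 1.0

    def test_empty_calls(self):
        truth = self._truth({3, 7})
        conf = ps.truth_report(truth, [])
        assert conf.sensitivity == 0.0 and conf.specificity == 1.0

    def test_counts_match_bruteforce_confusion(self):
        truth = self._truth({1, 2, 3})
        calls = [self._call(s) for s in (2, 3, 9)]
        conf = ps.truth_report(truth, calls)
        assert (conf.tp, conf.fp, conf.fn, conf.tn) == (2, 1, 1, 16)

    def test_out_of_frame_call_rejected(self):
        from propsel.errors import FrameError

        truth = self._truth({1})
        with pytest.raises(FrameError):
            ps.truth_report(truth, [self._call(99)])


def test_write_run_is_reproducible(tmp_path, star8_newick, default_table):
    spec = spec_for(star8_newick, 40, seed=3, table=default_table)
    aln, tree, truth = ps.simulate(spec)
    ps.write_run(tmp_path / "run", aln, tree, truth)
    assert (tmp_path / "run" / "alignment.fasta").exists()
    back = ps.read_codon_alignment(tmp_path / "run" / "alignment.fasta")
    assert back.sequences == aln.sequences
    events = (tmp_path / "run" / "truth_events.tsv").read_text().splitlines()
    assert len(events) - 1 == len(truth.events)
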