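# Methods

## The model

`propsel` detects selection acting on amino-acid *physicochemical
properties* in protein-coding genes.  The unit of evidence is a
nonsynonymous replacement inferred on a branch of a phylogeny; the question
asked of each replacement is not *whether* it changed the protein but *how
much* it changed each of a panel of physicochemical properties (hydropathy,
polarity, equilibrium constant of the carboxyl group, ...).

### Neutral expectation

The null model assumes completely random amino acid replacement subject
only to the structure of the genetic code.  For a genetic code we enumerate
every ordered pair of sense codons differing at exactly one nucleotide
position (the *single-step neighborhood*; 526 ordered sense–sense pairs in
the standard code, 508 in the vertebrate-mitochondrial code) and keep the
nonsynonymous pairs.  Every such pair is weighted equally — no
transition/transversion or codon-frequency weighting, matching the
neutrality assumption; weighting hooks would be a calibration of the null,
not of the data.

For each property, the absolute change |Δ| of every neighborhood pair is
computed and the interval [0, max |Δ|] is split into 8 equal-width
*magnitude categories*: category 1 the most conservative, category 8 the
most radical.  Bins are half-open `[lo, hi)` with the final bin closed, so a
magnitude equal to an interior edge belongs to the higher bin — a
deterministic tie-break.  The expected probability `p_k` of category `k` is
the fraction of nonsynonymous neighborhood pairs falling in bin `k`.
Because bins scale with the range, the categories are invariant under affine
transformations of a property's values.

Under the vertebrate-mitochondrial neighborhood three bundled properties
(`an`, `Pa`, `Bl`) have an empty category 7: no single-step pair falls in
that bin.  A category with zero neutral mass supports no test and scores
z = 0.  Observed events can still land in such a bin — see "out-of-support
events" below.

### Inferring replacements

Ancestral codon states are reconstructed per site by parsimony —
Hartigan's generalization of the Fitch algorithm, exact on multifurcating
rooted trees (the 3-taxon and 2-taxon group trees of a typical analysis
are multifurcations or single comparisons).  Reconstruction is on codon
states, not amino acids, so synonymous changes remain identifiable and are
excluded from the property statistics.  Determinism: on the top-down pass
the parent's state is kept when optimal for the child, otherwise the
lexicographically smallest codon in the child's optimal set is chosen.
Gap- or N-containing codons are wildcards (standard missing-data
treatment); a site with fewer than two unmasked taxa is skipped.

A codon change touching several nucleotides on one branch is a single
amino-acid replacement event.  When such an event's amino-acid pair is not
reachable by *any* single nucleotide change it lies outside the null's
support (it has no defined category probability) and is excluded from the
category statistics.  These pairs arise when parsimony compresses a
multi-hit history onto one branch; at within-clade divergences
(≲0.1–0.3 substitutions/site) they are a few percent of events.

### The z statistic

For each codon site, a window of `w` sites centered on it (clamped at gene
ends) is scored: `n` is the window's nonsynonymous event count and, per
property and category, observed count `O_k` is compared with the binomial
expectation:

    z_k = (O_k − n p_k) / sqrt(n p_k (1 − p_k))

`z > 3.09` (one-tailed normal, p ≈ 0.001) flags positive selection:
*positive-stabilizing* in conservative categories 1–3,
*positive-destabilizing* — the unambiguous signature of molecular
adaptation — in radical categories 6–8.  An exact binomial tail probability
is emitted alongside each z for audit.

Two site-level decision statistics are available:

- `category` — one call per (site, property, category) with z above the
  threshold (the classical per-category test);
- `band` (default) — the radical categories are pooled into a single
  observed-vs-expected test per (site, property), with
  `p_band = p6 + p7 + p8`.

The band statistic is the default because a selected site's radical excess
spreads over adjacent categories, and because in thinly-populated single
categories the normal approximation is strongly anticonservative: with
`p_k < 0.095` a *single* observed event already gives z > 3.09.  Pooling
raises both the sensitivity and the specificity of site detection.

### Whole-protein test

The gene-level statistic is the *signed sum* of per-site z-scores of a
property (by default over the destabilizing band; configurable to all
categories), compared with the same 3.09 cutoff; e.g. site scores
2, −2, −6, 4 sum to −2, below 3.09, so the protein as a whole is not called
positive.  Caveat: this sum is not standardized — its null standard
deviation grows with gene length — so at typical gene sizes nearly half of
neutral genes exceed a fixed cutoff.  The signed sum is retained as the
field's established whole-protein procedure; treat it as a ranking
statistic rather than a calibrated test.

### Cross-clade comparison

Groups (e.g. amphibians A, lungfishes L, coelacanths C) are analyzed
separately — no relationship between them is assumed — on a shared master
alignment coordinate system, so a site is identified across groups by
(gene, codon site).  For every property the report counts the sites flagged
positive-destabilizing in *all* groups of a grouping (A-L, A-C, L-C,
A-L-C).  Per-property cells must not be summed across properties: one site
is typically hit by several properties.  The deduplicated total per
grouping — the union over properties of the per-property intersection
sets — is reported separately, and the report enforces
`total ≤ column sum` as a checked invariant.

## The synthetic-data generator

Sequences evolve along a rooted tree (branch lengths in expected
substitutions per codon site) by a continuous-time jump process per
(branch, site): single-nucleotide changes proposed uniformly over the 9
codon neighbors, stop-creating changes rejected, everything else accepted
at baseline.  Rates are normalized so one unit of branch length yields one
expected substitution per site under neutrality at stationarity.

The neutral chain's rate matrix is symmetric, so its stationary law is
uniform over sense codons, and the root sequence is drawn from it.
Consequently the realized substitutions are, marginally, uniform draws over
the ordered sense–sense neighborhood pairs — *exactly* the analysis null.
This is the keystone internal-consistency property tying the simulator to
the expected distributions, and the reason the simulator deliberately has
no transition/transversion or codon-frequency bias by default.

Destabilizing selection is planted by multiplying the rate of every
nonsynonymous change falling in radical categories of a chosen property by
β ≥ 1, at chosen sites, on every branch inside a chosen clade; β = 1 is
exactly neutral.  Selection both tilts changes toward radical ones and
raises the substitution rate at the target sites, as adaptive substitution
does.  Determinism: one master seed with per-branch substreams keyed by the
child label, so adding taxa leaves other branches' histories unchanged.

What the generator does *not* emulate: indels and alignment error,
among-site rate variation, codon usage bias, transition/transversion bias,
and saturation-robust inference.  Tests passing on these simulations
therefore demonstrate internal correctness of the statistics and pipeline,
not robustness to the full complexity of real mitochondrial data.

## Statistical behavior, and the problem sizes used in the tests

Three properties of the method shape how the test-suite experiments are
sized; all were derived from the statistics, and the suite verifies them.

1. **Within-site event dependence.**  Successive substitutions at one site
   form a Markov chain — a replacement is often followed by its reversal,
   which repeats the same magnitude category — so category counts pooled
   over a site's history are overdispersed relative to the iid multinomial
   a chi-square test assumes.  The simulator-vs-null goodness-of-fit test
   therefore conditions on sites with exactly one realized event (a
   2-taxon tree with branch length 0.02 and 4×10⁵ sites gives >10⁴
   independent nonsynonymous draws), where the chi-square statistic is
   exactly calibrated.

2. **Calibration needs well-populated windows.**  The z-test's one-tailed
   tail mass at 3.09 approaches the nominal 10⁻³ only when windows hold
   enough events; binomial discreteness alone puts the per-cell
   false-positive rate near 0.5% at ~10 events per window and 0.25% at
   ~100–200.  The calibration experiment uses pairwise (2-taxon)
   comparisons — at most one inferred event per site, hence independent
   window counts — at divergence 0.3/site with 601-codon windows
   (~120 events each), where the measured rate is ≤0.5%.  At sparse
   windows (a handful of events) the per-category test is strongly
   anticonservative in small-p categories; this is inherent to the
   statistic, and the reason the band statistic and generous windows are
   the defaults.

3. **Parsimony compresses recurrent radical change.**  Under strong
   destabilizing selection a site toggles repeatedly between radical
   alternatives; on deep trees parsimony reconstructs the cheapest history
   and discards much of that toggling (in simulations at total tree length
   ~4, the recovered radical fraction can drop from 0.56 to 0.20).
   Recovery experiments therefore use a star clade (8 leaves, branch
   length 0.3), where each leaf lineage witnesses the signal
   independently; planted sites form a contiguous block (destabilizing
   selection produces local directional shifts in protein regions), which
   an 11-codon sliding window detects with sensitivity ≈0.75–0.8 and
   specificity ≈0.99 at the default threshold.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| genetic code | vertebrate mitochondrial | the analyzed genes are mtDNA-encoded; standard code selectable |
| z threshold | 3.09 | one-tailed normal cutoff, p ≈ 0.001 |
| window | 1 codon | sites pooled per test; use ≥11 for site detection, ≫100 events for calibrated per-category tests |
| category focus | 6,7,8 | destabilizing band entering calls and the whole-protein sum |
| site statistic | band | pooled radical-band test; `category` for per-category calls |
| β (simulator) | 1 | radical-rate multiplier at planted sites; β = 1 ⟺ neutral |

The bundled property table (20 properties × 20 amino acids) compiles
standard literature scales (Kyte–Doolittle hydropathy, Grantham polarity
and volume, Chou–Fasman conformational preferences, carboxyl pK, ...).
It is configuration, not code: any TSV with the same layout substitutes,
and all category machinery adapts because bins are derived from the table
itself.  Multiple-testing correction is deliberately off by default (an
optional Bonferroni flag exists); raw per-site tests mirror the field's
established usage, and the calibration analysis above is the honest account
of their error rates.

## Known limitations

- Parsimony undercounts events at high divergence and concentrates
  multi-hit histories into single branches; out-of-support exclusion
  mitigates but does not remove the bias.
- The whole-protein signed sum is unstandardized (see above).
- Site identity across groups requires one master alignment per gene; the
  pipeline checks only that site frames (codon counts) agree.
- The null conditions on the full code neighborhood, not on the codons
  present in the data; a data-conditioned null would improve calibration
  but absorbs composition shifts caused by selection itself, trading power
  for calibration.
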