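# Methods

This note records the models, parameter choices and numerical decisions
behind wgdlab, and what the simulation-based validation does and does not
establish.

## The inference chain

The package reconstructs paleopolyploidy evidence in four layers:
collinearity (anchors and blocks), synonymous divergence (NG86 Ks),
molecular-clock dating, and karyotype reconstruction. Each layer consumes
only the interface of the previous one, so real inputs (CDS FASTA + gene
tables + BLAST tabular) and simulated inputs are interchangeable.

## Synonymous divergence (NG86)

Per codon, each of the three positions contributes the fraction of its
three possible single-nucleotide changes that preserve the amino acid to
the synonymous site count; changes to stop codons count as nonsynonymous,
so synonymous + nonsynonymous sites total exactly 3 per codon. Differences
between codons differing at several positions are averaged over all
orderings of single steps, excluding pathways through stop codons (if every
ordering is blocked — impossible between sense codons under the standard
code — all pathways are counted). The multiple-hit correction is
Jukes–Cantor, ks = −(3/4)·ln(1 − (4/3)·ps); ps ≥ 3/4 is flagged saturated.
Only the standard genetic code is supported.

NG86 with JC was chosen over ML codon models (GY94/codeml) because it is
fully specifiable and checkable against an exhaustive codon-table oracle
(the test suite verifies exact agreement on all 61×61 codon pairs and on
500 random gene pairs), and it is adequate in the Ks ≤ 2 range where WGD
peaks of interest lie. Known bias: at synonymous positions dominated by
two-fold degenerate sites, true divergence saturates faster than the
four-state JC model assumes, inflating Ks by roughly 1–2% around Ks ≈ 0.3
and more toward saturation. The fast-vs-sequence-mode agreement test
allows exactly this margin.

Unequal-length pairs are aligned globally on their translations
(match 1, mismatch −1, gap −2) via Biopython's PairwiseAligner and
back-translated; gapped codon columns are dropped; fewer than 30 aligned
codons flags the pair undefined rather than producing a noisy estimate.

## Ks distributions and peak detection

Distributions keep values in (0.01, 5.0]: the lower cut removes allelic
and very recent tandem variation, the upper cut removes saturated noise.
Whole-paranome distributions down-weight large families (weight = 1/pairs
per family, families = connected components of the pair graph) so a single
expanded family cannot masquerade as a WGD peak; anchor and ortholog pairs
carry unit weight.

Peaks are found by weighted EM for 1-D Gaussian mixtures on ln Ks. The
component count k = 1..k_max is selected by BIC with effective sample size
Σw; each k is fitted from n_restarts quantile-spread initialisations
(seeded, deterministic); component sd is floored at 10⁻³ so degenerate
distributions remain fittable. A component's reported peak is
exp(mean_log) — its median on the Ks scale — matching common Ks-tool
practice; the lognormal mode would sit slightly lower. Confidence
intervals are percentile (2.5/97.5) bootstrap at fixed k; refits whose
adjacent component means lie closer than twice their width are counted as
collapsed, and a majority of collapsed refits triggers a warning that k
exceeds what the distribution supports.

## Rate calibration and dating

With E[Ks] = 2·r·T, each dated ortholog divergence (T, Ks peak) gives
r = Ks/(2T); multiple calibration points are pooled by arithmetic mean
(median available). The aggregation is a declared assumption — sources
reporting a single pooled rate rarely state it. No lineage-specific rate
adjustment is attempted; per-point rates spreading by more than 25%
trigger a heterogeneity warning instead. Ages are years internally, MYA
(2 decimals) at I/O boundaries, and peak CIs propagate linearly since
age = Ks/(2r) is linear in the peak.

When calibrating against a sister that shares an older WGD, cross-species
homolog lists mix speciation-aged orthologs with pairs split at the shared
WGD. The pipeline therefore calibrates on ortholog pairs only — in
simulation mode these are taken from the genealogy (pairs whose divergence
event is the speciation), which emulates reciprocal-best-hit ortholog
selection through a similarity channel whose noise is independent of the
Ks scatter. Selecting instead the minimum *observed* Ks partner
(`reciprocal_min_ks`, provided for real data lacking scores) is biased
low by extreme-value selection when a gene has several equally close
partners; prefer selection on alignment scores where available.

## Collinearity

Anchors live in 0-based gene-order rank space; base pairs appear only in
I/O, which makes chaining robust to intergenic-length variation.
Intragenomic pairs within 2 ranks on one chromosome are treated as tandem
duplicates and dropped before anchoring. Chains are scored by anchor count
(no distance penalties) and found by an O(n²) longest-chain DP per
chromosome pair and orientation, with consecutive-anchor gaps capped at
max_gap = 25 on both axes; blocks need min_block_anchors = 5. Both
defaults echo common collinearity-tool settings and are exposed in
configuration. Extraction is greedy — best chain over both orientations,
remove its anchors, repeat — with deterministic tie-breaks (earlier start
rank, then "+" orientation). Ties between equally long chains make the
literal block list axis-dependent; the tie-insensitive summaries (total
chained anchors, block-size multiset) are invariant and are what the tests
assert. On instances of ≤ 12 anchors the greedy total equals exhaustive
chain packing in all tested cases.

Syntenic depth counts, per reference gene, the blocks whose reference-side
span contains it; the modal nonzero depth of a k-fold duplicated genome
over an unduplicated relative is k. Paralogy clusters take the reference
side of cross-genome blocks as segments, merge overlapping segments, link
them through self-collinearity blocks, and report connected-component size
(distinct paralogous segments) and the number of merged counterpart
regions — the "four paralogous segments to two orthologous regions"
signature of a private WGD on top of a shared one.

## Karyotype reconstruction

Painting projects blocks against a reference (ancestral) gene order onto
each chromosome as rank intervals labelled by reference chromosome;
overlapping same-label intervals merge, intervals under
min_segment_anchors = 5 are dropped as noise, and adjacent same-label
segments merge. Fusions per chromosome = segments − 1; fissions per
ancestral label = carrying chromosomes − 1 (fission counting is a bonus —
fusion totals are the cross-species comparable quantity). The painting
reference should be unduplicated relative to the painted genome: against a
reference that shares a WGD, every chromosome legitimately maps to both
reference homeologs and apparent "fusion" counts are meaningless; the
demo pipeline therefore paints against a pre-WGD outgroup.

Homeolog grouping builds a graph of chromosomes weighted by
interchromosomal self-block anchor counts and extracts a greedy
maximum-weight matching (heaviest edge first, name-ordered tie-breaks).
After one WGD the expected group size is 2; two-round histories are
resolved by matching once (2n → n) and repeating on ancestor-projected
blocks. On post-WGD simulations the greedy matching attains the
brute-force optimal matching weight in all tested instances; adversarial
weight configurations where greedy is suboptimal exist in principle but
require near-tied linkage weights not produced by genuine homeology.

Retention tables collect per-block anchor counts (ancestral genes retained)
per species against a common reference; species are compared by classical
one-way ANOVA (scipy), requiring ≥ 2 species with ≥ 2 blocks each.

## The simulator

The simulator defines the statistical structure the analysis assumes — it
is the package's validation instrument, not a biological model of record.

State: one ancestral genome (n_chromosomes × genes_per_chromosome genes,
codons_per_gene random sense codons each) evolving along a schedule of
dated events, times in MYA strictly decreasing. Speciations copy the
genome into two lineages; WGDs (triplications) duplicate (triplicate)
every chromosome, then remove every gene copy independently with
probability fractionation_loss — so the expected gene count is
2G(1 − loss); fusions concatenate two chromosomes head-to-tail (painting
and fusion counting are orientation-agnostic, so the second chromosome is
appended unflipped); fissions split at a rank; inversions reverse a rank
interval and flip strands. Each lineage draws from its own RNG stream
derived from (seed, lineage name), so extending a schedule with a new
lineage does not perturb existing ones; identical config + seed gives
byte-identical outputs.

Sequence mode draws, per gene and branch, Poisson(r · t_years · S)
accepted substitutions (S = the gene's NG86 synonymous-site count), each
applied by proposing a uniform position and alternative base and redrawing
while the change would create a stop or — with probability 1 − omega — be
nonsynonymous. Proposals are redrawn until accepted (not discarded) so
that exactly the drawn number of substitutions lands; accepted synonymous
changes then fall on codons in proportion to their synonymous-change
counts, consistent with NG86 site weighting, and repeated hits are allowed
so the JC correction is meaningful and NG86 estimates converge to 2·r·T
(verified within 10% at 300 codons). The default omega = 0 keeps Ka ≈ 0
and Ks cleanly controlled. Fast mode ("ks_level") skips sequences and
emits 2·r·T × LogNormal(0, ks_scatter_sigma) per homologous pair
(σ default 0.15), which reproduces mixture peaks at the same locations as
sequence mode (within bootstrap CI plus the JC bias margin above).

Ground truth records realised events, each extant gene's ancestral gene
and chromosome, and the expected Ks of every homologous pair from the
exact divergence time of the pair's most recent common ancestor in the
gene-copy genealogy.

Defaults mirror the study conditions the package targets: rate
4.29×10⁻⁹ substitutions·site⁻¹·year⁻¹, WGDs at 15.14 and 122.31 MYA, a
sister divergence at 98.55 MYA, a 13-chromosome pre-WGD ancestor giving 26
extant chromosomes. Fractionation loss defaults to 0.2 — a free simulator
parameter chosen as a typical post-WGD retention level, not a measured
value; the karyotype-recovery conditions use 0.1. The default
ks_scatter_sigma = 0.15 produces peak widths comparable to empirical
anchor-pair Ks distributions at these ages.

What the simulator does **not** model: nucleotide-level rate heterogeneity
(every synonymous site evolves at one rate r), codon-usage bias, tandem
gene birth, transposable elements, gene conversion between homeologs, and
lineage rate variation. Passing tests therefore demonstrate that the
inference machinery is correct under clock-like, structurally clean
evolution at desk scale (hundreds to a few thousand genes); they do not
show robustness to rate heterogeneity, pervasive gene loss beyond simple
fractionation, or assembly artefacts in real genomes. The closed-form
dating identities, by contrast, are exact and scale-free.

## Problem sizes

Validation suites run at deliberately small scale, chosen as the smallest
sizes at which each statistical signature is unambiguous: mixture-peak
recovery uses 10,000 pairs per WGD (fast mode); depth/cluster patterns use
2–3 chromosomes × 50–60 genes; karyotype recovery uses 13 × 100 genes with
10% fractionation and 20 seeded rearrangement replicates; NG86 oracle
equivalence uses all codon pairs plus 500 random 100-codon gene pairs;
sequence-mode convergence uses 520 genes × 300 codons.
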