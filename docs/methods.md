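# Methods

This note documents the models, conventions and design choices behind
`ripcall`: what each stage assumes, which parameters matter, what the
synthetic data does and does not emulate, and where the genuinely open
decisions were made.

## Coordinates and counting

All coordinates are 0-based half-open (BED semantics); GFF3 input is
converted on read. Fragments are paired-end units (one interval per
joined mate pair, at most 3 kb long — longer records are dropped as
failed mate joins); counting is per fragment, not per mate. RPM uses the
total retained fragment count of a library as denominator. Overlap
counting is half-open; a fragment overlapping two features counts toward
both. Mapping uniqueness travels in the BED score field (1 = unique,
0 = multi-mapped) because the caller distinguishes unique-read from
all-read statistics.

## The region caller

The pipeline is strand-separated throughout, because forward and reverse
transcripts over the same locus are distinct annotations. Chaining uses
the inter-fragment gap (`next.start − prev.end`), with the 200 bp default;
"at least 8 reads" is interpreted inclusively (≥ 8) with a `strict`
switch for the > 8 reading, while the fold thresholds are strict (> 4)
— the two readings coexist in the method's published description and
cannot be distinguished from it. Fold enrichment adds a pseudocount of
one fragment to both raw counts before RPM normalization so that
zero-mutant regions have finite, conservative folds. Gene removal at the
final stage means *full containment* of a gene by the candidate
(any-overlap is available as `gene_removal="overlap"`); fragment-level
gene filtering at the start removes any overlap, either strand.
Candidate counts used in the fold and density filters are same-strand
counts, consistent with the stranded caller.

### The exact conditional NB test

Replicate counts per group are modeled as negative binomial with a
common dispersion φ estimated by method of moments on library-size
normalized counts (per-region, with a trimmed-mean common-dispersion
fallback where the moment estimate is zero). The test conditions on the
grand total T: the group-A total A is compared with
P(A = a | A + B = T) built from the two group-total NB pmfs under the
pooled mean. Group totals are NB with effective dispersion φ/n
(exact when per-replicate library sizes are equal within a group, an
approximation otherwise). At φ = 0 this reduces analytically to the
exact binomial split test with success probability L_A/(L_A+L_B) — the
suite verifies the identity to 1e−12 and checks φ > 0 against a
10⁶-draw Monte-Carlo oracle. Testing is one-sided toward wild-type
enrichment, since the pipeline only retains WT-enriched regions.

### Specificity

On null data (signal present identically in both genotypes) candidates
form but essentially none survive the fold and NB stages; the suite
checks final calls ≤ 5% of candidates over 50 simulations. Note that the
fold filters, not the FDR stage, do most of the work in this regime —
the NB stage guards the marginal cases.

## Domains

H3K9me2 fragments are counted in 100 bp windows with 50 bp steps; the
genome-wide median (including empty windows by default; a switch
restricts to non-empty) defines the keep threshold (strictly greater);
kept windows merge when they overlap or abut, and merged regions longer
than 1 kb are domains. Because windows at one-window gaps still abut at
this step size, a single below-median window does not split a domain.
The >median rule keeps a large minority of background windows whatever
the background level, so domain boundaries carry an irreducible outward
slop of roughly one window plus one fragment length; boundary-sensitive
evaluations should use domains a few windows long or more.

Edge profiles align both domain ends with the right end mirrored, so
"inside" is positive everywhere. The inside/outside analysis uses the
published windows (inside [start+50, start+250), outside
[start−250, start−50)) on left ends by default, with a both-ends mode;
domains closer than 250 bp to a chromosome start are skipped and
tallied.

## Metaprofiles

Feature bodies are rebinned to a fixed bin count by exact
fractional-base weighting (the interpolation is not specified in the
method's source; mean-of-covered-bases conserves total signal, and the
suite holds it to a per-base oracle at 1e−9 on exact multiples). Flanks
are kept at native resolution by default. Minus-strand rows are
reversed, so every row reads 5′→3′. Ratio signals are pseudocounted
bin-wise; methylation uses differences instead of ratios. Strand-bias
ratios add the RPM equivalent of one fragment to each strand, making
log-ratios finite and exactly antisymmetric under a global strand swap.

TE-edge analyses respect TE orientation (5′ = start of a plus-strand
TE). "Euchromatic" TEs are those whose midpoint lies in a 100 kb tile
with more gene than TE midpoints — the tile size is a package choice,
as the provenance of that selection is not published. Chromosome-scale
density counts feature midpoints in fixed windows. End-distance pairing
requires overlap ≥ 50% of the shorter feature (the denominator is a
package choice) and reports distances signed in the first set's
orientation.

## Fragment-length regression

Fragments are assigned to transcripts by containment. The model is an
isotonic regression of per-transcript mean fragment length on transcript
length, sampled on a grid; the inverse returns the shortest length
attaining a given fragment-length value, which resolves plateau ties
conservatively. The headline use mirrors the published asymmetry: the
curve is fitted on per-gene *means* but inverted at the *median* pooled
fragment length of the regions; this biases the longest RNA queries
downward (the guarantee tested is a ≤ 15% median relative error over an
RNA-length grid), and a consistent median/median mode is available via
`value="median_fragment_length"`.

## The synthetic data

The generator emulates the study design: two genotypes × two replicates
of stranded RIP fragments on a 10 Mb two-chromosome genome; 200 planted
transcribed regions (log-normal lengths, median 700 bp) partitioned into
consecutive internal RNAs (log-normal, median 200 nt); fragments are
sub-fragments of single internal RNAs, capped by a log-normal size
selection (median 250 nt) — this is what makes the RNA length
recoverable; 10× fragment-density enrichment over a 20 fragments/kb
uniform background in the wild type, none of it retained in the
polymerase mutant by default (`mutant_residual`); a configurable sense
fraction (`strand_mix`, default 0.75) and, for regions straddling TE
edges, a majority strand pointing into the TE body with probability
`edge_directionality`. Region-level counts are Poisson with an optional
gamma over-dispersion (`dispersion`, default 0.05) so the NB stage has a
matched generative model. Gene lengths are a mixture of a long bulk
(log-normal, median 1.5 kb) and a short ncRNA-sized class (15% at median
250 nt), anchoring the fragment-length curve across the whole range a
real annotation covers.

Background fragments are uniquely mappable with low probability
(`bg_unique_frac` = 0.02), while locus-specific (planted and genic)
fragments are unique at 95%. This mirrors the real system — intergenic
RdDM territory is repeat-dominated, and with 50 bp reads most background
alignments are non-unique, which is exactly why the caller distinguishes
unique from all reads — and it is also a regime requirement: the
published chaining thresholds (8 reads / 200 bp) and the caller's
boundary fidelity presuppose a sparse *unique* non-genic background;
a dense unique background would chain the entire genome.

H3K9me2 libraries plant fragments over domains, by default at
`h3k9me2_ratio` × background and, where an absolute density is wanted,
at `h3k9me2_domain_rate` fragments/kb; domain-recovery evaluations use
30 fragments/kb inside domains over a near-zero (0.05 /kb) background —
the "mostly-zero genome" regime in which sub-window boundary accuracy is
meaningful. H3 is near-uniform with a configurable elevation inside
domains; AGO4 follows the planted regions; siRNA libraries are 24 nt and
strand-balanced. Methylation is drawn per cytosine binomially on a fixed
lattice (no sequence is simulated), with contexts assigned 1:1:2
CG:CHG:CHH, CHH high inside regions in the wild type and low in the
mutant, and genotype-independent gene-body CG.

What the generator does *not* emulate: mappability and GC structure,
spliced or isoform transcripts, non-uniform background (rRNA or
organellar contamination piles), chromosome-scale compartments, or
sequence content of any kind. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated
generative model, not performance on real libraries — in particular the
false-call rate on real data depends on background structure the
simulation deliberately keeps simple.

Determinism: every library derives its generator from
(master seed, CRC32 of the sample key), so datasets are byte-identical
across runs and platforms for a fixed config.

## Problem sizes

The suite and the acceptance script run the full caller at the study
scale (10 Mb, ~10⁶ fragments total, a few seconds), 50 null simulations
at 2 Mb, the permutation calibration at 500–1000 datasets × 2000
permutations, and the Monte-Carlo NB oracle at 10⁶ draws; these sizes
give the calibration statistics small enough error to be meaningful
while keeping a full run around a minute.

## Known limitations

- The NB test approximates, and is not claimed equivalent to, the
  published package the original analysis used; its dispersion handling
  is method-of-moments, not shrinkage.
- Unequal per-replicate library sizes within a group make the
  conditional NB group-total distribution approximate.
- The permutation p-value is conservative under heavily tied statistics.
- BH-FDR is not idempotent (no step-up procedure is); the suite asserts
  monotonicity and exact agreement with the formula instead.
- Domain boundary accuracy is limited to about one window plus one
  fragment length by the >median window rule itself.
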