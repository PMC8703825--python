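# Methods

## The fingerprint model

TBP (tubulin-based polymorphism) profiling amplifies the first and
second introns of the β-tubulin (*TUBB*) gene family — six paralogous
loci in the *Lemna* species handled here — and sizes the amplicons by
capillary electrophoresis (CE).  A clone's observable is a set of
(region, fragment size in bp, peak height in RFU) triples.  The model
assumptions the whole package rests on:

- **Dominant scoring.**  A fragment size either appears in a profile or
  it does not; peak height carries no dosage information beyond noise
  filtering.  Markers are therefore binary, identified by (intron
  region, size bin).
- **Species allele pools.**  Each species draws its per-locus fragment
  lengths from a characteristic pool; conspecific clones share most of
  the pool, with some intraspecific variants confined to geographic
  subgroups.
- **Hybrid additivity.**  An interspecific hybrid carries both parental
  subgenomes (allotetraploid case), so its marker set is the union of
  one allele set from each parent — about 12 loci instead of 6.
- **Maternal plastid inheritance.**  The plastid spacer sequence of a
  hybrid is a copy of its seed parent's, so reciprocal crosses —
  nuclearly identical — separate on plastid distance.

## Peak scoring and binning (`matrix`)

Peaks below `min_rel_height` (default **0.05**) of the maximum height
of the same clone-and-region profile are discarded as baseline noise.
Surviving sizes are clustered per region by single-linkage: sorted
sizes are split wherever the gap between neighbours exceeds `tol_bp`
(default **1.0 bp**); the bin label is the rounded mean size.
Single-linkage was preferred over fixed integer bins so that a true
allele whose jittered sizes straddle an integer boundary stays one
marker; the cost is that two true alleles exactly 1 bp apart can chain
into one bin, which is a physical resolution limit of the assay, not a
parameter to fix.  Both defaults are package conventions — CE export
thresholds differ by instrument — and both are exposed.  Adjacent bins
that round to the same integer label are disambiguated with a `b`
suffix.  Monomorphic markers (present in all clones or none) are
dropped before any comparative analysis.

## Similarity, trees, ordination (`cluster`)

Genetic similarity between clones is Jaccard's index for binary data,
S = |A∩B| / |A∪B| over present-marker sets; the degenerate empty-union
pair is defined as similarity 1 with a warning.  Clustering needs a
dissimilarity, so the bridging convention is d = 1 − S.

The dendrogram is plain Saitou–Nei neighbor joining, written here
rather than delegated so replicate behaviour is fully specified:
Q-matrix ties break to the lowest (row, col) index pair and negative
branch lengths clamp to zero (deficits are simply absorbed), making the
output bit-reproducible.  On any additive distance matrix the inferred
tree's path metric equals the input (property-tested to 1e-9 against a
brute-force path-length oracle on random tree metrics, n ≤ 8, and
cross-checked against scikit-bio's NJ).

Bootstrap supports resample marker *columns* with replacement,
recompute Jaccard + NJ per replicate, and annotate each internal edge
of the **original** topology with the percentage of replicates whose
tree contains the same bipartition — supports map onto a fixed tree, no
consensus tree is built.  Rooting is at the midpoint of the outgroup's
pendant edge and preserves all path lengths.

PCA operates on the column-centered 0/1 matrix (not on a derived
similarity matrix), via SVD; variance proportions are σᵢ²/Σσ², and each
component's sign is fixed by making its largest-magnitude loading
positive.  Scores and proportions are verified against an independent
SVD oracle and scikit-learn.

## Species assignment and hybrid detection (`hybrids`)

A species' **pool** is the set of markers present in at least
`pool_freq` (default **0.8**) of its labelled reference clones — the
threshold keeps markers private to a geographic subgroup from
fragmenting the pool.  **Diagnostic** markers are those in exactly one
species' pool; species whose diagnostic set is empty are flagged.

Species assignment maximises Jaccard similarity between the clone's
marker set and each pool; ties are returned as unresolved rather than
broken arbitrarily.

Hybrid detection formalises reading "additivity" off an
electropherogram.  For a clone and unordered parent pair (A, B):

- coverage = fraction of the clone's markers inside pool(A) ∪ pool(B);
- shareA, shareB = counts of A's and B's diagnostic markers carried.

The verdict is *hybrid* for the best pair when coverage ≥ `min_cov`
(default **0.9**) and shareA, shareB ≥ `min_diag` (default **2**):
one-marker dropout is tolerated, but multiple independent diagnostic
alleles from *each* parent are required, so a single-parent explanation
necessarily leaves ≥ `min_diag` markers of the second parent
unaccounted for.  These numeric thresholds are package conventions (the
original call was made by eye from complete additive profiles) and are
exposed as flags.  The search is restricted to pairs of reference taxa;
there is no de-novo parent discovery and no ploidy inference.

Maternal assignment computes, per candidate parent, the mismatch
proportion over aligned non-gap plastid sites (unequal-length inputs
are globally aligned first with Biopython's PairwiseAligner) and
requires a unique minimum below `max_dist` (default **0.1**); this
replaces database best-hit lookups with distance to user-supplied
parental references, avoiding an external dependency and version drift.

## Reclassification rates (`reclassify`)

The morphology-vs-TBP contingency table counts clones by label pair
over a declared taxon list; clones with either label outside the list
are excluded and reported (the survey's three always-correct minor
species are outside the five focal taxa by default, matching how the
printed table was built).  Row, column and overall misidentification
percentages are (total − diagonal)/total × 100, rounded **half-up** to
one decimal to match printed precision.

## Intron haplotypes (`haplotypes`)

Positions are 1-based alignment columns.  Polymorphic-site detection
treats the gap character as a state — indel columns are polymorphic —
while ambiguous `N` is ignored.  A haplotype is an equivalence class of
identical state vectors over the polymorphic sites, named in discovery
order with the reference's class first.  Substitution counting exposes
two indel conventions, because published tables mix them:
`exclude_gap_sites` (default) counts differing sites where neither
state is a gap; `count_events` additionally counts each maximal run of
gap-mismatch sites as one indel event.  Hybrid subgenome sequences are
assigned to the nearest parental haplotype by mismatch count over the
parental site list; ties stay unassigned.  Clones whose chromatograms
were superimposed (length-variant heterozygotes) are represented as
missing and excluded from haplotype calling.

The shipped fixtures encode the published site patterns and clone
assignments; full-length alignments are reconstructed by placing those
states on a shared constant synthetic background, which preserves every
derived quantity (site counts, partitions, substitution counts) while
inventing nothing about the unpublished invariant columns.

## The synthetic generator (`simulate`)

The generator emulates the data-generating process the analysis
assumes, with all randomness flowing from one integer seed through
named `numpy.random.Generator` instances:

- **Pools**: 6 loci × 2 regions of archetypal lengths (222–455 bp,
  inside the 150–800 bp CE window), per-species offsets drawn from
  N(0, `divergence`) rounded to `offset_step` (default 1 bp); after
  drawing, every species is guaranteed ≥ 1 diagnostic allele per region
  (a minimal deterministic shift repairs collisions).  Default
  `divergence` is **8 bp** — large enough that four species are fully
  separable, of the order of the inter-species length differences seen
  in these introns.  One species carries a fixed extra 250 bp region-1
  fragment, mimicking a retrotransposed pseudogene amplicon.
- **Clones**: one peak per locus per region, heights uniform 800–4000
  RFU; with probability `het_prob` (default **0.1**) a locus emits a
  doublet at +3 bp.  Hybrids are allotetraploid by default (full
  additive union), with a homoploid option (random one-of-two allele
  per locus); their plastid record is a verbatim copy of the maternal
  parent's reference; each subgenome contributes one intron sequence to
  its parent species' alignment.
- **Plastid/intron references**: per-species substitutions in disjoint
  site blocks of a shared ancestor (6 plastid substitutions/species ≈
  1.4 % spacer divergence), plus three intra-species intron haplotypes
  at frequencies 0.6/0.3/0.1.
- **CE noise**: zero-mean Gaussian size jitter (`jitter_sd`, default
  **0.3 bp**, a typical CE sizing repeatability; the true value for any
  given instrument is unreported) and independent peak dropout.

What it does **not** emulate: allele-pool history (pools are specified,
not evolved under mutation/coalescence), stutter or pull-up artifacts,
height-dependent dropout, partial digestion, or primer-site mutations.
Passing tests therefore demonstrate correctness of the scoring and
calling logic under the stated model, not robustness to every failure
mode of real electropherograms.

A known interaction worth stating: a +3 bp doublet variant can
coincidentally equal another species' diagnostic allele, so at
`het_prob` > 0 an occasional pure clone can carry enough foreign
diagnostic markers to be miscalled — the exact-recovery guarantee
(100 % species, hybrid, parent-pair and maternal recovery) holds for
homozygous profiles at zero CE noise and full divergence, and the test
suite checks it under those conditions.

## Problem sizes and numerical choices

The reference synthetic cohort is 4 species × 12 clones + 12 hybrids
(6 per reciprocal direction of one cross) = 60 clones; the degradation
grid spans jitter {0, 0.5, 1.5, 3} bp × dropout {0, 0.1, 0.3} with 3–4
cohorts per cell, and evaluates the monotone trend on seed-averaged
marginals with a 0.02 allowance for residual sampling noise.  Bootstrap
examples use 50–1000 replicates.  Exact comparisons (NJ path metrics,
PCA proportions) are asserted at 1e-9; probabilistic ones (half-normal
jitter magnitude, dropout rate) at 3 standard errors.

## Limitations

- The marker counts of any real survey depend on instrument-specific
  peak-calling thresholds; without the raw electropherograms only the
  downstream statistics (misidentification rates, hybrid counts,
  haplotype tables) are reproducible, and those are what the fixtures
  pin down.
- Dominant markers cannot give allele dosage; allotetraploid vs
  homoploid status is out of scope.
- The hybrid caller only considers parent pairs drawn from the
  reference pool set.
- `misid_rates` rounds half-up; a printed table produced by truncation
  will differ in the last decimal.
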