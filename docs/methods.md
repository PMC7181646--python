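# Methods

## Coordinate conventions

All intervals are 0-based, half-open `[start, end)` (BED-native).  The
midpoint of an interval is `floor((start + end) / 2)`; an even-width
window therefore places `width // 2` bases left of the midpoint.  These
two conventions are applied uniformly, so every offset and distance in
the package is defined without off-by-one ambiguity.  Windows that
would cross a chromosome boundary are clipped (shortened), not shifted,
so peak counts are preserved and midpoints stay put.

## Co-occupancy and distances

Peaks are compared through fixed-width windows centered on their
midpoints (default 100 bp, the standard choice for near-base-pair
ChIP-exo resolution).  Two windows co-occur when they share at least
one base, i.e. when the midpoints are less than `window` bp apart for
the default equal-width case.  Because the overlap fraction of "the two
sets" has no canonical denominator, the result reports the fraction of
A peaks with a partner, the fraction of B peaks with a partner, and the
pooled union fraction.

Peak-peak distances are midpoint distances of co-occurring pairs.  Two
pairing rules are provided: `nearest` (default; one distance per A peak
with at least one partner) and `all_pairs` (every co-occurring pair,
exactly symmetric in A and B).  The nearest rule is the default because
multi-overlaps are rare at ChIP-exo peak densities and a per-peak
statistic is easier to interpret; both are computed by the same sweep
and the choice is a config parameter.  An empty overlap yields an
explicitly undefined median (None/NaN), never 0.

`consensus_merge` unions overlapping peaks within each replicate and
keeps maximal runs of bases covered by at least `min_support` distinct
replicates.  It is an interval-level consensus; re-calling peaks from
merged raw alignments is out of scope, and results on real data should
be read with that substitution in mind.

## Chromatin-state enrichment

A segmentation is a labeled partition (gaps allowed; uncovered
positions report as `Unannotated`).  Each peak/region is assigned the
state at its midpoint — a single deterministic rule chosen over
maximum-overlap because regions are small relative to segments;
midpoints on a segment boundary belong to the following segment
(half-open).  Per-state frequencies of the sample are compared to an
IgG background as `log2((f_s + eps) / (f_c + eps))` with pseudocount
`eps = 1e-4`, recorded in the result.  The pseudocount only matters for
states absent from one of the sets; it maps "absent from both" to
exactly 0.  Swapping sample and control negates every value exactly.

## Tag pileups

Tags are consumed as 1-bp BED intervals marking 5' read ends.  Each tag
is assigned to its nearest anchor (ties to the left-most anchor) and
counted at the strand-oriented offset `pos - anchor` (sign flipped for
minus-strand anchors), provided the offset lies in
`[-half_width, half_width - 1]`.  The TSS pileup ranks genes by
expression (ties broken by gene id for determinism), splits them into
equal-count bins — quartiles by default, the usual choice when the
source data say only "sorted by expression" — and accumulates one
profile row per bin, highest expression first.  Total counts always
equal the number of in-range assigned tags; this conservation is
asserted in tests.

## Regulatory domains and gene linking

Basal domains are `[TSS - 5000, TSS + 1000)` for plus-strand genes and
the mirror image `[TSS - 999, TSS + 5001)` for minus-strand genes.
Extension follows the published basal-plus-extension association rule:
each domain grows outward until it reaches another gene's basal domain
or 1 Mb from the TSS, whichever is closer; a gene's own basal domain is
always kept even when a neighbor's basal domain overlaps it.  The
stopping boundary is the first foreign basal edge encountered, which a
per-base oracle in the test suite verifies on random mixed-strand
annotations.

Regions are linked to genes by any-overlap with the extended domain (a
region may link 0, 1 or several genes).  The binomial region-set test
uses the midpoint rule instead — a region counts as a hit when its
midpoint falls in the union of the gene set's extended domains — with
`p = P(X >= k)`, `X ~ Binomial(n_regions, f)` and `f` the covered
genome fraction.  The tail probability is evaluated by direct summation
of the binomial terms in log space (log-gamma per term, compensated
summation); tests pin it to an exact rational-arithmetic oracle at
1e-12.

## Expression and qPCR utilities

FPKM is `count * 1e9 / (length * total_mapped)`.  BH adjustment is the
textbook step-up (`adj_(i) = min_{j>=i} p_(j) n / j`, capped at 1).  DE
thresholding uses strict `padj < alpha` (replicated designs) and
additionally `|log2FC| >= 1` for unreplicated designs.  ChIP-qPCR
quantities come off a least-squares standard curve
`Ct = slope * log10(amount) + intercept` fitted to an input-DNA
dilution series; each IP is normalized to input (percent input) and
expressed as fold over the IgG control.  The input fraction cancels in
the fold and the fold is invariant to affine relabeling of the dilution
axis; both identities are tested.

## Synthetic data: what is planted and how

The generator emulates the inputs of a two-factor ChIP-exo / RNA-seq
integration study on a scaled-down genome.  Defaults (the study
conditions for all recovery tests):

| parameter | default | meaning |
|---|---|---|
| genome | 4 chromosomes, 50 Mb | desk-scale stand-in for a mammalian genome |
| genes | 4,000, min 2 kb TSS gap | dense enough that extended domains tile the genome |
| states | Promoter .05, Enhancer .12, Transcribed .23, Heterochromatin .40, Repressed .20 | genome proportions; segments ~2 kb mean length |
| state weights | 2 / 4 / 0.6 / 0.5 / 0.41 | factor-peak placement multipliers; weighted proportions sum to exactly 1, so the planted log2 enrichment vs uniform IgG is exactly log2(weight): 2.0 on enhancers, 1.0 on promoters |
| peaks | 5,000 per set (A, B, IgG), widths 20-60 bp | ChIP-exo-scale narrow peaks |
| overlap fraction pi | 0.22 | floor(pi * n_A) A peaks receive a B partner |
| offset distribution | discrete Laplace, median 94 bp, scale 3 bp, sign equiprobable, truncated to [0, 99] | midpoint offset of planted partners |
| tags | 100,000; 20% uniform background; Laplace spread 50 bp around TSS; per-gene weight exp(2 * rank) | expression-dependent promoter signal |
| DE truth | (541, 49) | enhancer-linked genes passing padj < 0.05 per condition |

Design notes:

- **Offset truncation.** With 100-bp windows, only pairs with midpoint
  offsets below 100 bp are observable as co-occurring, so magnitudes
  are drawn from a discrete Laplace centred on the planted median and
  truncated to `[0, window - 1]` by resampling.  The magnitude median
  stays exactly at the planted value, every planted partner remains
  recoverable, and the recovered median is an unbiased readout.  A
  reported median of 94 bp under 100-bp windows necessarily sits near
  the window-imposed ceiling; the generator reproduces that situation
  faithfully rather than planting an untruncated distribution whose
  wide tail would silently delete a third of the planted pairs.
- **Spacing.** All independently placed midpoints (A and unmatched B)
  keep a minimum separation of 3x window, so no accidental window
  overlaps dilute the planted fraction; partner peaks are the only
  peaks within window reach of an A peak.  Consequently the realized
  overlap fraction is exactly `floor(pi * n_A) / n_A`.
- **Unbiased state placement.** Per-state peak counts are drawn first
  as an exact multinomial over weighted proportions; positions are then
  sampled inside the chosen state, and min-separation conflicts are
  resampled *within the same state*.  (Rejecting into the global
  distribution instead would systematically deplete crowded states —
  measured as ~0.07 log2 units on enhancers — so the two steps are kept
  separate.)
- **Quota segmentation.** Segment lengths are geometric (mean 2 kb) and
  the next state is drawn proportionally to its remaining bp budget, so
  realized per-state bp match the configured proportions to within
  rounding.
- **DE planting.** Exactly n1 (n2) enhancer-linked genes receive
  `padj < 0.05` in condition 1 (2); the condition-2 set is a subset of
  condition 1, emulating loss of regulation after knockdown.  Unlinked
  genes are DE at a 10% background rate, which cannot perturb the
  planted intersections.  DE tables are planted directly rather than
  simulated from counts and refit, keeping DE-model internals out of
  scope while making the intersection counts exactly recoverable.
- **Streams.** All randomness derives from one seed through named
  SeedSequence children (genome, peaks, expression, tags, de), so every
  stage is individually reproducible and the emitted bundle is
  byte-identical across runs.

What the generator does *not* emulate: read-level noise and mapping
artifacts, peak-caller uncertainty (peaks are placed, not called),
copy-number or mappability structure, correlated replicate structure,
and realistic LD-like clustering of motifs.  Passing recovery tests
therefore demonstrates the correctness of the integration arithmetic —
not robustness to upstream noise sources, which enter a real analysis
through the peak caller and aligner.

## Problem sizes and tolerances

Recovery tests run 20 seeds at 5,000 peaks per set on the 50 Mb
genome.  At that size the per-seed standard error is ~0.03 log2 units
for the enhancer enrichment and ~0.14 for the enhancer-promoter gap
(the promoter occupies only 5% of the genome), so recovery of the gap
within +-0.2 is asserted on the across-seed mean; the overlap fraction
and median offset are deterministic given the construction and are
asserted per seed (binomial 95% CI and +-2 bp respectively).  The
binomial tail and BH tests use exact oracles (rational arithmetic and
statsmodels) at 1e-12.  Brute-force interval oracles run on 1,000
random instances.

## Known limitations

- `consensus_merge` approximates replicate consensus at interval level.
- Peak-state assignment defaults to the midpoint rule; a max-overlap
  rule is available (`state_frequencies(..., assign="max_overlap")`)
  but the pipeline uses midpoints throughout.
- The binomial region-set test assumes regions are independent draws,
  as in the published association rule; clustered regions inflate
  significance.
- The pipeline treats DE tables as given; no count modeling, shrinkage
  or library-size normalization is performed.
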