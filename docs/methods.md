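# Methods

This note documents the models and procedures implemented in `epidomains`,
the choices behind their defaults, and what the synthetic-data tests do and
do not demonstrate.

## Coordinate conventions

All regions are 0-based half-open (`[start, end)`), the BED convention, on
chromosome names compared as opaque strings (`chr1` ≠ `1`). Merging joins
two same-chromosome intervals when the gap between them is ≤ the stitch
window (so bookended intervals merge at gap 0); the merge is a transitive
closure and is idempotent. Overlap between two intervals requires ≥ 1
shared base by default; an optional minimum-overlap (bp) and
reciprocal-fraction parameter are available, since published protocols in
this area rarely state an overlap fraction.

## Super-enhancer calling (ranked ordering)

H3K27ac peaks are stitched within a window (default 12,500 bp; 5,000 bp is
exposed via configuration because both values circulate in the literature
for this kind of analysis and the two give different region sets — neither
is privileged here). Optional TSS exclusion (off by default) removes peaks
fully inside TSS ± 2,500 bp before stitching. Each stitched region is
scored by input-corrected signal area,

    score = max(0, area(treatment) − area(input)),

where area is Σ(overlap bp × track value) over the region. Clipping at 0
keeps the rank order defined when input exceeds treatment. Regions are
ranked ascending by score (ties broken by genomic coordinate so output is
reproducible), both axes of the rank–score curve are rescaled to [0, 1]
(x = rank/n, y = score/max score), and the cutoff is the unscaled score at
the first rank where the discrete slope between consecutive scaled points
exceeds 1. Regions scoring strictly above the cutoff are super-enhancers.
This is the standard "tangent" construction used by ROSE-style callers,
implemented as a first-crossing scan rather than a tangency optimisation:
the scan is deterministic, and the rescaled construction makes the cutoff
invariant under positive rescaling of all scores (verified by a property
test). Degenerate inputs: a flat score vector yields the common score as
cutoff and zero super-enhancers; a single region is returned as typical.

## Broad H3K4me3 domains

Broad domains are the widest top fraction (default 5%) of H3K4me3 peaks:
peaks are ranked by width descending with ties broken by (chrom, start)
ascending, and exactly `ceil(top_fraction × n)` peaks are kept. The ceiling
rule makes the output size a deterministic function of (n, fraction) for
every n ≥ 1, which is asserted as a law in the tests.

## Grade classification across a panel

The domain sets of all panel samples are merged (gap 0 by default, to avoid
chaining unrelated domains) into union regions; occupancy[r, s] = 1 iff
sample s's set overlaps union region r by ≥ 1 bp. A region is **common**
if present in every sample; **HGU** (High-Grade-unique) if present in at
least `min_in_group` High-Grade samples (default: all of them) and at most
`max_in_other` Low-Grade samples (default 0); **LGU** symmetrically; and
**other** otherwise. The defaults are the strictest reading of "unique
to"; the thresholds are configurable because softer readings (any-subset
presence) are also defensible. A row that would satisfy both the HGU and
the LGU rule under permissive thresholds is labelled *other*, which keeps
the classification exactly symmetric under swapping the group labels
(property-tested). Overlap between the two domain types (super-enhancer vs
broad H3K4me3) is assessed per category at ≥ 1 bp, with the shared count
reported from the super-enhancer side.

## Differential enrichment

The differential caller is deliberately simple, exact plumbing rather than
a dispersion-modelling method: replicates are pooled within condition, and
for region i with pooled counts (t_i, c_i) and pooled library sizes (T, C)
the null treated proportion is p0 = T/(T+C); the p-value is the exact
two-sided binomial test of t_i successes in t_i + c_i trials at p0
(scipy's minlike two-sided convention). The fold-change uses pseudocount 1
on the counts only — `log2(((t+1)/T) / ((c+1)/C))` — so log(0) never occurs
without distorting the test itself. FDR is Benjamini–Hochberg across all
regions and directions are assigned at FDR < 0.1 (the conventional
threshold for this kind of ChIP-seq contrast). Swapping condition labels
negates every fold-change and preserves every p-value exactly; a region
with zero pooled counts gets p = 1 and fold-change 0. This statistic makes
no claim of reproducing DESeq2/edgeR-style shrinkage; on Poisson counts
with ≥ 4-fold planted effects at mean 20 and two replicates per condition
it reaches sensitivity ≥ 0.9 with false-discovery proportion well inside
the nominal level, and on null data it flags essentially nothing — both
measured by the acceptance script, not assumed.

Location annotation uses precedence promoter > intragenic > distal
intergenic, with a strand-aware promoter window of (−2000, +500) bp around
the TSS (a common default; no published window was being matched). Gene
assignment links every gene whose TSS lies within 100 kb of a region's
edges (distance 0 if the TSS is inside), following GREAT-style regulatory
domains. Expression comparisons between gene categories use Welch's
unequal-variance t-test, two-sided, with the convention that two
zero-variance identical samples give p = 1; categories with fewer than two
expressed genes are excluded with a warning.

## TAD calling (simplified TopDom)

For a symmetric contact matrix at a fixed bin size (default 40 kb), the
binSignal at the gap between bins g and g+1 is the mean of the w×w diamond
{m[i, j] : g−w < i ≤ g < j ≤ g+w} clipped to the matrix edges (w defaults
to 5 bins, TopDom's own default). Candidate boundaries are strict local
minima of this profile; each candidate is kept only if a one-sided
rank-sum test of its diamond cells against the pooled diamond cells of the
w flanking gaps on each side gives p < 0.05. The original TopDom's
piecewise-linear fitting step is not reproduced — local minima plus the
rank-sum filter give a defined, testable caller — so boundary positions
can differ from TopDom's by a bin on noisy data, which is why recovery is
asserted within ±1 bin. Domains are the maximal runs between consecutive
boundaries; runs shorter than `min_domain_bins` (default 2) are merged
into the neighbour across the gap with the smaller binSignal. A
minima-free (e.g. constant) matrix yields a single domain and no
boundaries. The boundary bin is recorded as the first bin of the
downstream domain, and boundary regions are the boundary bin extended by
±20 kb (`[bin_start − flank, bin_end + flank)` — the anchor is stated
explicitly because "±20 kb of the boundary" is ambiguous between bin
centre and bin edges).

## Boundary permutation test

Observed = number of features overlapping any flanked boundary region.
Each of n_perm (default 1000) permutations draws, uniformly **without
replacement**, the same number of bins as there are boundary bins (the
"auto" rule; a fixed count such as a study-specific bin total can be
supplied instead, since published analyses sometimes permute a fixed
dataset-dependent number of bins), flanks them identically, and counts
feature overlaps of the union of the drawn regions. The empirical p-value
uses the add-one rule p = (1 + #{perm ≥ observed})/(n_perm + 1), which is
never zero and is unbiased in the Phipson–Smyth sense; the z-score is
(observed − mean)/sd of the permutation counts. Results are
bit-reproducible given the seed.

## Synthetic data generator

The panel generator emulates a seven-sample study (3 High-Grade, 4
Low-Grade cell lines) carrying two domain types. Planted common / HGU /
LGU regions appear in exactly the samples their category prescribes;
background regions (default 50 per sample per domain type) are
**sample-specific** — each appears in exactly one sample — so under the
default strictest uniqueness rule they classify as *other* and the planted
category counts are recovered exactly on noise-free data. Background
occupancy shared across all samples would be indistinguishable from
planted common domains at the classification stage, which is why the
generator does not produce it. Regions are placed by seeded rejection
sampling with all edges ≥ 25 kb apart (twice the default stitch gap), so
stitching can never merge two distinct truths; placement failure on a too
small genome is an explicit error. Signal is piecewise-constant per
region: baseline 1.0, planted regions multiplied by the contrast (default
20×), with multiplicative log-normal noise (σ default 0.2) because ChIP
enrichment is ratio-scaled. Super-enhancer-like regions are emitted as
clusters of three constituent peaks so the stitching step does real work.

The contact-matrix generator plants block-constant TADs
(within-block mean = contrast × between-block mean, default 10:1) with
multiplicative log-normal noise and explicit symmetrisation. The treatment
generator draws Poisson counts per region per replicate (mean 20, two
replicates per condition by default) and scales a chosen fraction of
regions by ±effect_fold in the treated samples. The expression generator
gives genes in affected categories a mean log2 fold-change of
`group_effect` plus Gaussian noise.

What the synthetic data does **not** emulate: read-level sampling noise,
fragment-size effects, mappability and GC bias, copy-number distortion of
input, inter-chromosomal contacts, distance-decay within TADs, and
realistic peak-width distributions. Passing the planted-recovery tests
therefore demonstrates correctness of the algorithms under their stated
models, not calling performance on real ChIP-seq or Hi-C libraries.

## Problem sizes and determinism

The test suite and the acceptance script run the full category structure
of the study design (38/61/224 super-enhancer and 228/177/302 broad-domain
categories across 7 samples), a 150–200-bin contact matrix with ten
planted blocks, 2,000 regions for the differential power and null checks,
and 1,000 permutations for the enrichment tests (199 per replicate in the
100-replicate null-calibration loop, which only needs resolution below
0.05). Everything is single-threaded and seeded; the command-line `all`
run writes byte-identical output trees for identical config + seed, which
is asserted by hashing in the tests.

## Known limitations

- The binomial differential statistic ignores biological overdispersion;
  on real replicated data it will be anticonservative relative to
  DESeq2-style inference.
- The TAD caller's significance filter uses a rank-sum test on correlated
  diamond cells; its 0.05 level is a filter heuristic, not a calibrated
  error rate.
- The ranked-ordering cutoff is sensitive to the maximum score; a single
  extreme outlier region raises the cutoff for all others, as in any
  ROSE-style caller.
- BED-family parsing covers BED3/6, narrowPeak, broadPeak and bedGraph;
  bigWig input is out of scope.
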