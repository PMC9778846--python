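# Methods

This note records the models, conventions and numerical decisions behind
`calcmicro`, in the order the pipeline applies them.

## Synthetic study generator

`simulate_profiles` draws a taxon-by-sample count table that mirrors the
design the pipeline targets: four host groups defined by subspecies and
altitude band — western lowland (300–500 masl), low-altitude Grauer's
(600–1000 masl), high-altitude Grauer's (1001–2100 masl) and mountain
(3000–3800 masl) — with 8 calculus samples per group by default, two
processing batches ("new" and "published") assigned alternately, 8
extraction/library blanks split across batches, and 4 museum controls.
Coordinates are drawn in subspecies-specific boxes so that geographic and
altitudinal distances are partially confounded, as they are in museum records.

**Count model.** Taxa belong to oral (60), environmental (25) and laboratory
(20) pools with log-normal base weights. Per sample, the composition is drawn
from a Dirichlet distribution with parameter `concentration × p`, where `p`
is the base composition after group, batch and spike effects act
multiplicatively on relative abundances (structural zeros null the weight
outright), and counts are multinomial at a log-normal depth
(`exp(N(14, 0.5))` ≈ 1.2 M reads for calculus; blanks ≈ 60 k; controls ≈
160 k). The default `concentration = 50` places realistic overdispersion on
the compositions. Calculus samples are dominated by the oral pool with
sporadic low-level laboratory (30% of cells) and environmental (70%)
carryover; blanks are dominated by laboratory taxa (present in every blank,
as reagent contaminants are); museum controls share the environmental pool at
a distinct concentration (20) with trace oral carryover — this makes the
exceedance filter genuinely discriminative rather than trivial.

**Effect realism.** Because the per-taxon Dirichlet parameters are small at
`concentration = 50`, the expected log-ratio shift under a spike is
digamma-nonlinear and does not equal the nominal effect; at high
concentration the bias vanishes and the mean CLR difference between affected
and unaffected groups converges to `e·(1 − 1/m)` (the exact CLR geometry
factor for m taxa). The effect-realism property test therefore runs at
`concentration = 5000` and checks against that value at a 3-standard-error
tolerance.

**Marker design.** The default spike/structural-zero lists implement an
altitude gradient: six *highland* markers are structurally absent below the
1000 masl divide, six *lowland* markers are the mirror image, and four
*graded* markers are present everywhere with effects rising with band (0,
0.15, 1.8, 1.95 log units). Within-band differences are deliberately small
(0.15): the target significance pattern has the within-band pairs
(mountain vs high Grauer's; western vs low Grauer's) null. Two further oral
taxa carry a 2.0 log-unit batch effect (the dataset-artefact channel the
two-pass filter must catch), and one oral genus is also placed on the
contaminant list to exercise the damage-rescue path.

**Damage model.** Reads are simulated against an internally generated
reference; when damage is on, C→T substitutions occur at distance *k* from
the 5′ end with probability `p1·decay^(k−1)` (defaults 0.1 and 0.5) and G→A
mirror-image at the 3′ end, plus uniform background errors (0.001). In
barcode mode, position 1 is suppressed (factor 0.25) and the decay profile
starts at position 2, reproducing the attenuated first-position damage that
in-line barcodes cause.

**What the generator does not emulate.** Reads are not taxonomically
classified — tables are simulated directly, so classifier biases (database
incompleteness, misassignment between relatives) are absent. Blank
contamination is compositionally independent of the samples processed
alongside them; real cross-contamination is correlated. Damage is uniform
across taxa rather than age-structured. Passing tests therefore demonstrate
the correctness and calibration of the statistical machinery under a faithful
study *design*, not robustness to classifier artefacts.

## QC and decontamination

Boundary semantics follow the printed rules exactly: the read-count gate
excludes calculus samples with *fewer than* 300,000 reads (300,000 is kept;
blanks and controls are exempt); the oral gate excludes proportions *lower
than* 3%; the abundance filter zeroes cells *below* 0.005% (a cell at exactly
0.005% survives); museum exceedance and MAG exceedance use strict "higher
than"; the isolation-source screen is inclusive at ≥25%; MAG quality tiers
are strict (>90/<5, >50/<10).

The blank-enrichment score is a one-sided Fisher exact (hypergeometric tail)
probability rather than the chi-square statistic some decontamination tools
use: exactness makes the score oracle-checkable, and the calling semantics
(contaminant iff score < threshold, per dataset, unioned over datasets) are
unchanged. Extraction and library blanks are pooled as the control class;
museum controls are never used for prevalence scoring — they have their own
filter. The frequency/DNA-quantity mode of decontamination is not
implemented (input DNA quantities are not part of the data model).

Relative abundances for the 0.005% and exceedance filters are recomputed on
the table as it stands when the step runs (post-prevalence); this is
switchable in the sense that each step is callable separately on any table.
`decontaminate` consumes the blanks and museum controls and returns the
filtered table restricted to calculus samples. This is what makes the
pipeline idempotent: re-running it on its own output finds no controls (the
prevalence and exceedance steps no-op with warnings) and the remaining steps
are naturally idempotent. Retaining controls in the output would break
idempotence — once a control's dominant environmental mass is removed, its
trace oral carryover would be inflated into spurious exceedance on a second
pass.

## Damage authentication

Profiles store both substitution types at both ends for the first K = 25
positions. The authentication rule evaluates, per end, whether more than
`min_hits − 1 = 1` of the first 3 positions (2–4 in barcode mode) have
frequency strictly above 0.02. Some descriptions pair C→T with the 3′ end;
the convention reported by the standard profiling tools — and the one the
simulator produces — pairs C→T with 5′, so that pairing is the default and
the swapped assignment is available as `pairing="literal"`. The overall call
is lenient (authentic if either end passes), consistent with the
retain-when-untestable stance of the list filter; an AND mode is provided.
Whether the published rule pooled ends or required both is not stated in the
sources this mirrors, so neither mode is asserted as "the" original. Taxa
with fewer than 10,000 classified reads are untestable, and untestable taxa
are retained by the list filter.

## Community statistics

Zero replacement before CLR uses a global pseudocount of half the smallest
nonzero relative abundance in the table (configurable). Presence for Jaccard
is count > 0 on the decontaminated table. On tables restricted to a small
marker panel, structural absences can empty a sample; `allow_empty=True`
assigns such samples the uniform pseudocount composition (a CLR zero vector)
instead of erroring, and the stratified contrasts use this mode.

PERMANOVA uses sequential (Type-I) sums of squares in caller order — read
count, then dataset, then the biological factor, so the biological term is
conservative — with unrestricted row/column permutation of the distance
matrix and `p = (1 + #{F* ≥ F}) / (1 + n_perm)`. An exact mode enumerates all
n! permutations for small n. Permuted statistics are compared with a relative
tie tolerance of 1e-9·max(1, |F|) so that permutations equivalent to the
observed layout count as ties despite float accumulation. Degenerate
(all-zero) distance matrices return F = 0, p = 1. Rank-deficient designs
raise an error naming the offending term.

Alpha diversity uses bias-corrected Chao1 (robust when F2 = 0; the classic
form is a flag) and base-e Shannon. The `sqrt(500 − x)` transform presumes
Chao1 < 500; values ≥ 500 raise an explicit domain error rather than being
clamped. "Normalised richness" is available as optional rarefaction to a
common depth, off by default and flagged in the output.

## Differential abundance

Log-ratios use a +1 pseudocount. Within-taxon multiple testing across the
m − 1 ratio tests uses Benjamini–Hochberg at α = 0.05 (Bonferroni is the
option for the reported per-taxon posthoc p, matching how such results are
usually printed). The 0.9 quantile of W is computed over taxa with W > 0 by
default (over all W as an option): with sparse tables most W are zero and the
all-W quantile would degenerate to 0. Detection requires both the W rule and
the Bonferroni posthoc (`require_posthoc=True`), or structural absence; the
structural-zero call additionally requires ≥25% presence in some other group
to prevent singleton-driven calls. The full ANCOM-II taxonomy of outlier and
sampling zeros is simplified to this structural-zero rule. W is invariant to
rescaling a sample's counts up to the +1 pseudocount; the property test uses
a zero-free, large-count table where the invariance is exact in practice.

## Ecology and diet

Grauer's samples split at ≤1000 masl (low) vs >1000 masl (high); other
subspecies keep their labels. Geographic distances are Euclidean on raw
(latitude, longitude) degrees — matching the common usage this mirrors, not
great-circle — and the controlled matrix in partial Mantel tests is
log(d + 1), which admits zero distances. Mantel permutation tails are
one-sided (greater). Pearson is paired with Jaccard distances and Spearman
with Aitchison, as is conventional. The stratified contrasts test the five
across- and within-band pairs with the dataset covariate entered first and BH
adjustment within each metric. The expected altitude pattern is read off the
Aitchison metric: the marker panel is defined by differential abundance, and
with three strong positives among five BH-adjusted tests the two null pairs
sit near an effective raw-α threshold, so demanding the pattern
simultaneously on the coarse presence/absence metric as well would fail a
substantial fraction of perfectly healthy replicates. Jaccard results are
always computed and reported alongside.

Diet filtering starts at the genus-level eukaryote table (upstream read
re-classification is out of scope): museum-control genera are removed
outright, cells under 10 reads are zeroed, and genera are kept when their
*family* appears in the known-food reference list. The diet ANCOM uses the
same detection rule with total dietary reads as the covariate.

## Problem sizes

The test suite and acceptance script run at desk scale by choice: 32 calculus
samples (8 per band group), ~125 taxa, ~1.2 M reads per sample; 100
replicates for damage calibration; 400 null simulations per permutation
procedure (p resolution 1/200 at n_perm = 199); 25 replicates at n_perm = 999
for pattern recovery. These sizes put the binomial noise on every reported
rate well inside the tolerances being checked.

## Known limitations

- The NNLS source estimator is a linear stand-in for EM-based source
  tracking; it is exact on noiseless mixtures of the reference profiles but
  has no uncertainty model and attributes correlated sources greedily.
- `Ancom` with covariates uses a Gaussian linear model on log-ratios rather
  than a rank test, so heavy-tailed noise inflates its error rates slightly.
- The damage profiler assumes gapless terminal alignments for position
  counting; indels inside the first K positions shift the reference-aligned
  index (as the standard tools also do).
- MRM supports a single predictor matrix (the use case here); multiple
  predictors would need the full pseudo-t machinery.
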