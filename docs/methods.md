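# Methods

## Physical model

DNA deformability is parameterized at the dinucleotide-step level by the six
diagonal stiffness constants of the helical-space energy model — twist, tilt,
roll (kcal/(mol·deg²)) and shift, slide, rise (kcal/(mol·Å²)). Off-diagonal
(coupled) terms are deliberately out of scope: the model consumes only the
diagonal constants, and consumes them as *input* (a TSV table); deriving them
from molecular-dynamics trajectories is not part of this package. Diagonal
stiffness is strand-symmetric, so every table must satisfy
K(XY) = K(revcomp(XY)); the loader enforces this to 1e-9 and will complete a
table listing only the 10 unique steps. The channel order
(twist, tilt, roll, shift, slide, rise) is frozen package-wide and recorded
in file headers.

The shipped default table is a synthetic representative set (its filename and
header say so): the magnitudes match MD-derived constants channel-wise, but
the values are not a published parameterization. Any real table in the same
format is a drop-in replacement, and the table checksum is carried through
trained models so that training and scanning cannot silently mix parameter
sets.

### Profiles and windows

A sequence of length L yields L−1 step vectors. Steps touching a non-ACGT
base (assembly gaps, IUPAC ambiguity) are masked rather than erroring —
genome scans must tolerate gaps — and masked steps are excluded from all
averages. Soft-masked lowercase bases are ordinary bases for the physics;
they matter only to the repeat filter.

Windows are 0-based half-open bp intervals; a window [s, s+w) owns steps
s..s+w−2 and its value is the unweighted arithmetic mean of its unmasked
step vectors ("averaged linearly" is read as the plain mean; no smoothing
kernel). A window whose valid-step fraction falls below `min_valid`
(default 0.9; the handling of gaps is otherwise unspecified in the source
material) is invalid and propagates NaN. Defaults: 500-bp windows, 50-bp
stride (the analysis unit is stated as 500 bp; the stride is a package
choice, configurable).

## Classifier

### Feature space

A candidate TSS is described over a −250/+900 bp span (the region where
promoter and background stiffness profiles differ most) tiled with 500-bp
windows every 50 bp: 14 windows × 6 channels = 84 features. Antisense
candidates are handled by reverse-complement symmetry: the antisense step
series is the reversed sense series, so minus-strand grid windows are read
from the forward cumulative sums at mirrored coordinates — an exact
identity, not an approximation, given the table invariant.

### Reference profiles and distance

Each class (promoter / background) is summarized by the sample mean and
covariance of its training feature vectors; antisense training examples are
reverse-complemented first. The covariance is:

* full sample covariance + λI when n ≥ D+2, with λ = 1e-6 · trace/D floored
  at 1e-9 (the floor keeps the degenerate identical-training-set case
  invertible);
* diagonal (per-feature variance + λ) below that, with a warning.

Distance is the Mahalanobis form √((x−μ)ᵀΣ⁻¹(x−μ)) via Cholesky
factorization. The score of a candidate is d_background − d_promoter;
label "promoter" iff score > 0, with an exact tie falling to background
(conservative calling).

The full-covariance mode matters: tiled 500-bp windows at 50-bp stride
overlap by 90%, so their sampling noise is strongly correlated. A diagonal
covariance ignores that correlation and blurs localization; the full
covariance whitens it and sharpens the score peak at the true TSS. This is
why the synthetic benchmark trains with 250 examples per class (> D+2 = 86).

### Scanning and peak calling

Both strands are scanned at a configurable stride (default 50 bp) wherever
the full grid fits; candidates whose grid overlaps an invalid window are
emitted as no-calls. TSS calling is greedy non-maximum suppression: local
score maxima strictly above τ, accepted in descending score (ties: leftmost,
then '+'), suppressing further candidates within 1200 bp of an accepted call
*regardless of strand* — a promoter-composition locus can peak on both
strands and should yield one call. With τ unset, the 95th percentile of the
genome-wide valid score distribution is used (the "high-confidence" cut; the
original confidence cutoff is not numerically specified anywhere, so it is a
package default, configurable).

### Candidate filters and regions

The high-confidence set keeps calls whose position is ≥ 1200 bp from every
annotated TSS (position-to-position, strand ignored, inclusive at 1200) and
whose 1200-bp tested region is ≤ 70% repeat-masked (strictly more rejects).
Masking comes from soft-masked sequence or an optional mask BED; running a
repeat masker is out of scope, as are PCR-primer uniqueness checks.

Regions derived from a call (0-based half-open, strand-aware — upstream
follows the strand): `core_promoter`/`tested_1200` span −1000/+200
(minus strand: [tss−200, tss+1000)), `expanded_2000` spans ±1000 bp. Regions
running off the chromosome are truncated with a warning flag.

## Tag 5′-end profiling

CAGE/RNA-seq inputs are assumed already quality-filtered and
replicate-merged; the package starts from 5′-end position records,
deduplicates them per cell line on (chrom, position, strand) — removing
amplification artifacts — and matches each distinct 5′-end to a candidate
region only if it lies inside [start, end) *and* on the same strand. The
distance runs from the region's biological 5′-end: start on '+', end−1 on
'−' (the minus-strand convention is a package decision).

Distances are aggregated into 100 percent-distance bins,
bin = max(1, ⌈d/w⌉) with w = length/100: left-open/right-closed with
distance 0 in bin 1. This is the unique convention that simultaneously puts
1000 bp of a 1200-bp region in bin 84, 750 bp in bin 63, and 1000 bp of a
2000-bp region in bin 50. Counts stay raw integers (with n_regions and
n_matched exposed, so per-region normalization can be applied downstream);
when a length is not divisible by 100 the last bin absorbs the remainder,
with a warning.

`relocate_tss` shifts each region's TSS by a strand-aware offset (default
−500 bp = upstream) and rebuilds ±1000-bp expanded regions, reproducing the
re-location analysis in which an upstream-displaced tag peak moves onto the
expected on-TSS bin.

## Enrichment and signal summaries

Per-feature 2×2 incidence tables (region set with/without the feature vs a
background transcript list) are tested with the two-sided Fisher's exact
test (minimum-likelihood summation, via scipy; one-sided available by flag).
The odds ratio is reported as (a·d)/(b·c), with Haldane's +0.5 on every cell
only when a zero cell occurs — the p-value is always the exact one. The
family-wise threshold is Bonferroni α/m over the m features actually tested;
features with a zero margin are reported as degenerate rather than aborting
the batch.

Signal summaries: per-base means of sorted non-overlapping bedGraph tracks
over regions, with uncovered bases counted as 0 (a package decision);
mean cluster-overlap counts (≥ 1 bp intersection of half-open intervals);
and the fraction of regions whose mean intensity strictly exceeds a
threshold in *any* cell line (reference settings 10 and 50). The
predictor×activity cross labels a region L+ iff its normalized reporter
ratio strictly exceeds 3-fold (an optional 10-fold flag isolates the
high-activity regime), yielding subsets 1–4 = PS+L+, PS+L−, PS−L+, PS−L−.

## Synthetic data

The generators produce the statistical structure the pipeline assumes, not
real promoter biology — no CpG islands, TATA boxes, nucleosome signals or
chromatin context. Passing tests therefore demonstrate correctness of the
machinery and well-calibrated statistics under the stated model, not
performance on real genomes.

* **Genome.** Background is a first-order (default iid-uniform) base chain.
  Each planted promoter rewrites the full −250/+900 grid span around its TSS
  with a composition mixed toward an A/T-rich target. Plants carry internal
  structure — full mixture weight over the 5′-side 500-bp core, 1/3 of it
  distally — because a compositionally homogeneous span is provably
  strand-ambiguous and position-degenerate under a reverse-complement-
  symmetric table (every placement inside it has the same expected profile);
  the two-block structure emulates the position-dependent profile real
  promoters show and makes TSS localization well-posed. Planted TSSs sit on
  the 50-bp scan lattice, ≥ 2400 bp apart. Optional lowercase decoy
  stretches exercise the repeat filter.
* **Effect size** is defined in profile space: the Euclidean distance
  between expected promoter-core and background 500-bp window means, each
  channel whitened by the background window-mean standard deviation
  (treating steps as independent draws; the mild overlap correlation of
  adjacent steps is ignored in this normalization). The mixing weight is
  calibrated to the requested effect by bisection — closed-form expected
  step frequencies make this analytic for iid chains — and caps at the
  target composition's ceiling with the realized effect recorded in the
  truth output.
* **Benchmark conditions** (the defaults): 120-kb genome, 20 plants, effect
  12 (strong-signal regime, near the default composition's ceiling of ~13),
  250 training examples per class so the classifier runs in full-covariance
  mode. Under these conditions, scanning at 50-bp stride with the
  95th-percentile τ recovers ≥ 90% of plants within one stride at ≥ 80%
  precision, and with effect 0 the score AUROC is chance level (0.5 ± 0.1
  over 20 seeds). Problem sizes were chosen so the whole suite runs in
  seconds while leaving the statistics comfortably resolved.
* **Tags** place each 5′-end at a chosen peak offset (probability =
  peak weight, ± jitter) or uniformly in the region, on the region strand
  except for a stated opposite-strand decoy fraction. **Incidence tables**
  draw null features hypergeometrically from a binomial background pool
  (exactly the Fisher null) and inflate one planted feature's region count.
  **Tracks** are piecewise-constant with optional coverage gaps.
* All randomness flows through `numpy.random.default_rng` (PCG64, integer
  state), so every artifact is byte-stable for a fixed seed across
  platforms.

## Numerical choices and limitations

* Shrinkage λ = 1e-6·trace/D (floor 1e-9); Mahalanobis via Cholesky; ties in
  peak calling resolved leftmost-then-'+'; BED-style 0-based half-open
  coordinates throughout.
* The grid anchors features to a candidate TSS; a pure anchored-grid scan is
  one of two readings of the original 500-bp analysis unit (the other being
  unanchored window scoring), chosen here because it makes the −250/+900
  discriminative span and the window unit compose cleanly.
* Localization precision is limited by the 500-bp window: at moderate effect
  sizes the score ridge around a plant is flat relative to
  sequence-sampling noise, and sub-stride localization is not attainable.
* The per-region tag matching is O(regions × tags) via vectorized filtering;
  adequate for validation-scale region sets, not for transcriptome-wide
  profiling.
* No attempt is made to reproduce counts or rates that depend on wet-lab
  data or external genome/annotation resources.
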