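# Methods

## The problem

A bulk tumor specimen is a mixture of cancer cells (fraction ρ, the tumor
*purity*) and diploid tumor-adjacent cells. From paired low-pass tumor and
normal whole-genome sequencing (down to ~0.5× depth), `puriploid` jointly
infers purity, tumor ploidy ψ (length-weighted mean total copy number of
the tumor cells), per-segment allele-specific integer copy states (nA, nB),
and, where integer states fail, a per-segment subclonal (clonal) fraction.
It abstains when the genome carries no usable copy-number signal.

The package also implements the downstream comparison layer used when many
purity estimators are applied to one cohort: consensus aggregation across
pathologists and across molecular methods grouped by analyte, and
concordance statistics between estimators.

## Forward model

For a segment with total tumor copies n in a sample of purity ρ, the
expected read depth is proportional to the cell-population average
`2(1−ρ) + ρ·n`. Observed logR is median-centered, so the model carries a
scale parameter ψ (the copy number at the centering point):

    E[logR | n] = log2( (2(1−ρ) + ρ·n) / (2(1−ρ) + ρ·ψ) )

A heterozygous SNP on a segment with state (nA, nB) has expected mirrored
B-allele fraction

    E[BAF | nA, nB] = max(b, 1−b),   b = ((1−ρ) + ρ·nB) / (2(1−ρ) + ρ·(nA+nB))

A segment carrying one subclone at clonal fraction f mixes its altered
state with the baseline state (diploid (1,1), or tetraploid (2,2) after a
whole-genome duplication, WGD): `n_eff = f·n_alt + (1−f)·n_base`.

Reported tumor ploidy is always recomputed as the length-weighted mean of
the assigned integer totals, so it does not depend on the centering
convention.

## Exact degeneracies of the model

Write c = 2(1−ρ)/ρ. Expected depth ratios take the form (c+n)/(c+ψ) and
mirrored BAF (c/2+nA)/(c+n). Two families of parameter transformations
leave **all** expectations invariant:

1. **Doubling**: (ρ, ψ, S) ≡ (ρ/(2−ρ), 2ψ, 2S); c is preserved. This is
   the classical whole-genome-duplication ambiguity.
2. **Shift by two**: (ρ, ψ, S) ≡ (ρ′, ψ+2, S+(1,1)) with
   c′ = c − 2 (upward) or c′ = c + 2 (downward). Exact for *every* state
   when shifting up; shifting down is blocked exactly where a state would
   need a negative allele count — i.e. by allele-floor states with nB = 0
   (hemizygous or deep losses, copy-neutral LOH) and by the exclusion of
   the (0,0) state.

Consequences built into the package:

* (0,0) (homozygous deletion) is excluded from the fitted state table:
  megabase-scale biallelic loss is not viable, and admitting it removes the
  main observable anchor of WGD.
* A genome-doubled tumor whose states all have nB ≥ 1 is analytically
  indistinguishable from a lower-ploidy genome; no estimator can recover
  it. WGD detectability requires nB = 0 anchor segments, which the WGD
  simulation catalogue therefore contains ((2,0) deep loss, (4,0) post-WGD
  copy-neutral LOH — both common in genome-doubled tumors).
* Within a degenerate family the lowest-ploidy member is reported
  (parsimony), matching how such ties must be resolved in practice.

## Fitting objective

Per segment, at each (ρ, ψ) grid point, the best integer state minimizes a
composite cost with three ingredients:

1. **logR evidence** — variance-scaled squared residual
   `(L − E[logR])² / σ_L²`, with σ_L the within-segment standard error
   combined (in quadrature) with a systematic floor: 0.02 on the coarse
   grid (absorbing the ψ-step quantization of 0.05) and 0.01 after local
   refinement (residual GC wiggle). This term rejects models that absorb
   real signal as noise — without it, "everything diploid at purity ≈ 1"
   explains any faint low-purity profile.
2. **Allelic evidence** — the deviance of the expected BAF under the
   segment's folded binomial-mixture profile likelihood (below), tempered
   by a quasi-likelihood dispersion factor of 3 because pooled BAF
   estimates scatter beyond their nominal binomial errors (residual
   allelic heterogeneity within segments). For *copy-neutral* states
   (total equal to the baseline's), any pooled BAF between 0.5 and the
   clonal expectation is reachable by subclonal mixing with the balanced
   baseline without moving logR, so those states are scored against the
   best point of that interval.
3. **Copy-space parsimony** — the squared distance between the
   back-transformed real-valued copy number `(2^L·(2(1−ρ)+ρψ) − 2(1−ρ))/ρ`
   and the integer state, weighted by 3, plus a mild karyotype prior
   (0.05 per copy step from the scale's own balanced baseline). The
   back-transform amplifies noise by ~1/ρ, so degenerate low-purity fits
   and doubled fits (whose noise doubles while integer spacing stays at
   one copy) pay for their extra flexibility automatically.

Per-segment costs are length-weighted (∝ bin count) and capped at 50: a
segment at a genuinely subclonal copy number is a model violation, not
evidence against the whole solution.

The fit is a two-stage grid search: coarse (ρ step 0.01 over [0.05, 1.0],
ψ step 0.05 over [1.2, 6.0]), then local refinement of the best point of
every half-copy ploidy band (ρ step 0.0025, ψ step 0.004) with the tight
logR floor — competing solutions differ by ~0.01–0.03 in logR, below the
coarse quantization.

## Solution selection

Among refined candidates within 5% of the best score, the lowest
state-derived ploidy wins. The pick is then walked down the alias ladders
while the data carry no evidence for a duplicated karyotype:

* **Reducibility descent** — if restricting the candidate's segments to
  exact k-fold states (k = 2, 3; both alleles divisible by k) costs less
  than 5 score units, the profile is expressible at ploidy/k and the best
  lower-ploidy candidate is taken. Exact doubled images restrict at < ~1;
  genuine WGD anchors cost > ~15. Segments the unrestricted fit itself
  cannot place on an integer (residual > 12, subclonal) are excluded — a
  single subclonal segment absorbed by the finer doubled lattice must not
  make the doubled solution look irreducible.
* **Shift descent** — the exact shifted-down image (ψ−2 at the purity
  solving c′ = c+2) is evaluated directly; if it scores within 35% it
  replaces the pick. Allele-floor blockers cost far more than 35% when
  the duplication is real.

These rules replace a single score margin, which cannot work: the doubled
lattice is a strict superset of the doubled image of any lower solution
and therefore *systematically* over-fits noise by 10–50%.

## Mirrored-BAF estimation at 0.5×

Per segment, SNP alt counts are modelled as a two-sided binomial mixture
(the alt allele sits on the major or minor haplotype with probability 1/2):
`P(k|d) = ½·Bin(k; d, b) + ½·Bin(k; d, 1−b)`. Depth-1 SNPs have constant
mixture likelihood and are uninformative; only depth ≥ 2 SNPs contribute
(~9% of SNPs at 0.5×). The estimator is the profile-likelihood maximum on
a grid over [0.5, 0.999]; the full profile-likelihood curve is kept
in-memory and consumed by the fitter as an exact deviance. When inference
starts from a SEG file (where only summaries survive), a quadratic
approximation with per-side profile-likelihood errors is used instead —
the folded likelihood is flat toward 0.5 (zero Fisher information at the
fold), so the lower-side error is much wider for near-balanced segments.

Known bias: near allelic balance the MLE is biased upward (boundary
folding); the deviance scoring is immune to this because it compares
likelihoods, not point estimates.

## Segmentation

Changepoints come from penalized binary segmentation of corrected logR per
chromosome (least-squares gain vs a BIC-style penalty estimated from the
median absolute successive difference; minimum 5 bins). Allelic balance vs
copy-neutral LOH is invisible in logR (equal totals), so two allelic
passes follow:

* a refinement pass splits segments at decisive changepoints of the
  per-SNP folded deviation |alt/depth − ½| (gain > 2.5·var·log n, ~99.9th
  null percentile; minimum 40 informative SNPs);
* a heterogeneity guard drops the pooled BAF (keeping depth information)
  of segments that still look allelically mixed (best split gain >
  1.6·var·log n) — a pooled estimate over such a mixture would be
  confidently wrong.

A position-free two-component mixture test was evaluated and rejected: at
depth ~2 the folded count distribution of a mixture is exactly matched by
a single intermediate value, so only positional structure identifies
mixtures.

## GC correction

One LOESS curve of combined tumor+normal counts against GC fraction
(bias assumed shared by the pair), median-normalized; corrected logR is
the median-centered log2 ratio of corrected counts. Insert-size and other
positional biases are not modelled.

## Abstention

A call is withheld (mirroring how DNA-based estimators fail on real quiet
genomes) when:

* **quiet genome** — the confidently aberrant genome fraction is below
  0.01. A segment counts as aberrant only when its total differs from the
  baseline *and* its logR deviates > 3σ from the baseline expectation, or
  it is confidently allelically unbalanced (deviance vs balance > 12, a
  level the null boundary chi-square mixture essentially never reaches).
  The confidence qualifiers block two degenerate sponges: balanced
  folding flukes relabelled as partial LOH, and the "whole genome lost one
  copy at purity 0.03" solution. The score profile across the purity grid
  being flat (range < 5% of its median) also triggers this reason.
* **poor fit** — best capped score above 15.

## Subclonal fractions

After a call, segments whose residual exceeds 9 are re-examined: the
effective copy number is recovered by inverting the depth model at the
called (ρ, scale), and the clonal fraction f solves
`n_eff = f·n_alt + (1−f)·n_base` over the adjacent-integer pair, with the
baseline-side integer chosen nearer the genome baseline (2, or 4 when the
called ploidy exceeds 3). Segments on integers keep f = 1. Only one
subclone per segment is modelled.

## Simulator

The generator emulates exactly the data regime the caller targets:
segment-level truth with integer allele-specific states (event catalogues
per scenario; events overwrite, tile, and merge), optional WGD baseline,
optional single subclone per altered segment (f ~ U(0.3, 0.8)); bins of
100 kb with GC ~ N(0.45, 0.06) clipped to [0.30, 0.65] and a mild
multiplicative quadratic GC bias; Poisson counts (optional gamma-Poisson
overdispersion) scaled so the genome-wide mean matches
`coverage × bin_size / read_length` (read-length equivalent 100 bp; at
0.5× and 100 kb this is 500 reads per bin); binomial het-SNP alt counts
(150 SNPs/Mb) at depth Poisson(coverage × local mixture), with random alt
phase per SNP.

Desk-scale defaults: 8 chromosomes × 60 Mb (4,800 bins, ~72,000 SNPs per
genome). What the simulator does *not* emulate — mappability and
replication-timing bias, insert-size effects, sequencing error, multiple
subclones per segment, correlated noise along the genome — bounds what the
benchmarks show: passing them demonstrates correct inversion of the stated
admixture model at low-pass noise levels, not robustness to every artifact
of real libraries.

## Benchmarks (computed by tests/test_acceptance.py and scripts/acceptance.py)

* Recovery grid: ρ ∈ {0.2, 0.4, 0.6, 0.8} × target-ploidy cells
  {1.8 (deletion-heavy), 2.0 (drift-balanced), 3.6 (genome-doubled)}, 20
  replicates per cell at 0.5×; draws carry ≥ 5 aberrant segments, and WGD
  draws ≥ 1 odd-total and ≥ 1 nB=0 segment (the detectability conditions
  derived above). Calls are compared against each draw's realized truth.
* Quiet-genome abstention (50 CNA-free vs 50 aberrant tumors), WGD
  disambiguation (20 + 20), the analytic alias identity, brute-force
  oracles for BH / exact binomial / exact rank-sum, GC-bias removal on
  20,000 bins, exhaustive consensus-algebra checks, and byte-level
  determinism of the bundled demo configuration.
* The acceptance script runs the same computations with 10 replicates per
  recovery cell and 30/15 replicates for the abstention/WGD rates.

## Consensus and concordance conventions

* Pathology ranges are snapped per review to the decile grid (half-up),
  collapsed to the midpoint of the snapped range, then the per-sample
  estimate is the median across reviews and sections (midpoint-then-median
  was chosen over pooling all endpoints; for ranges spanning an even
  number of deciles the readings coincide).
* Analyte consensus is the median of the non-missing mapped methods;
  missingness is never imputed (it is analytically meaningful — quiet
  genomes).
* Agreement between molecular consensus and pathology uses an absolute
  tolerance of 0.15 on the purity scale; the under/over-estimation
  binomial test runs on samples deviating jointly in one direction.
* Pairwise-complete Pearson/Spearman correlations (≥ 3 pairs per cell);
  Ward clustering on 1 − R with name-sorted leaves for determinism.
* Rank-sum tests are exact up to 50 per group without ties, otherwise
  normal approximation with mid-ranks and tie-corrected variance; BH
  families are per-panel (across tested genes; within estimator across
  features).

## Known limitations

* Purity below ~0.1 or above the grid, and coverage below ~0.25×, are
  outside the validated regime.
* A prominent subclonal segment can still attract a genome-doubled
  interpretation when clonal anchors are few; the residual cap and
  alias-evidence exclusion mitigate but do not eliminate this.
* CN-LOH blocks shorter than ~5 Mb inside balanced segments are invisible
  at 0.5× (they fall below the allelic changepoint power) and surface only
  as extra BAF dispersion, which the dispersion tempering absorbs.
* The SEG-file entry point uses the quadratic BAF approximation, which is
  slightly weaker than the in-memory deviance path used by the pipeline.
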