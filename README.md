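# puriploid

Tumor purity, ploidy and subclonality from **low-pass** (down to ~0.5×)
paired tumor–normal whole-genome sequencing — plus the comparison layer
needed when many purity estimators meet one cohort: consensus estimates
across pathologists and across molecular methods grouped by analyte, and
concordance statistics between estimators.

It is written for cancer-genomics analysts who need a desk-scale,
fully-testable purity caller: every stage can be driven by the built-in
tumor–normal admixture simulator with known truth, so the whole pipeline
is verifiable without any external data.

## The model

A bulk tumor is an admixture of normal diploid cells and tumor cells at
purity ρ. A genomic segment with total tumor copies *n* has expected
(median-centered) depth log-ratio

    E[logR] = log2( (2(1−ρ) + ρ·n) / (2(1−ρ) + ρ·ψ) )

where ψ is the tumor ploidy scale, and a heterozygous SNP on a segment
with allele-specific state (nA, nB) has expected mirrored B-allele
fraction

    E[BAF] = max(b, 1−b),  b = ((1−ρ) + ρ·nB) / (2(1−ρ) + ρ·(nA+nB))

`puriploid` inverts this model by an exhaustive two-stage grid search over
(ρ, ψ) with per-segment integer state assignment, scoring each candidate
by a composite of logR evidence, a folded binomial-mixture BAF deviance,
and a copy-space parsimony term. Whole-genome duplication is handled
explicitly: the model's exact aliases (doubling and copy-shifts) are
resolved by parsimony descents that keep a duplicated karyotype only when
allele-floor segments demand it. On "quiet" genomes — no usable
copy-number aberrations — the caller abstains instead of guessing, the
behavior real DNA-based estimators exhibit as missing values.
`docs/methods.md` derives the degeneracies and documents every numerical
choice.

## Worked example

Simulate a 0.5× tumor–normal pair at purity 0.65 and call it:

```
$ puriploid run --config examples/demo.cfg --out-dir demo_out
truth purity=0.65 ploidy=2.474; called purity=0.6524999999999996 ploidy=2.474 abstained=False reason=none
```

`demo_out/` then contains `bins.tsv` (binned tumor/normal counts with GC),
`snps.tsv` (het-SNP allele counts), `truth.tsv` (the simulated truth),
`segments.tsv` (SEG-style segments annotated with fitted nA/nB and clonal
fraction) and `purity_call.tsv`:

```
sample  purity  ploidy   abstained  reason  score     score_gap
demo    0.6525  2.47396  0          none    0.510907  0.314101
```

The call matches the simulated truth (ρ = 0.65, ψ = 2.474): `purity` is
the cancer-cell fraction, `ploidy` the length-weighted mean tumor copy
number recomputed from the fitted integer states, and `score` the
length-weighted mean per-segment residual of the selected solution.

The same stages are available individually (`puriploid simulate`,
`gc-correct`, `segment`, `infer`) and as library functions
(`puriploid.call_sample`, `puriploid.fit_grid`, ...). Estimator-comparison
workflows use `puriploid consensus` (pathology-range collapsing, analyte
medians) and `puriploid concord pairwise|agreement|mutations|screen`
(correlation matrices with Ward ordering, ANOVA across methods,
under/over-estimation classification with an exact binomial direction
test, mutation-stratified purity with exact rank-sum tests and
Benjamini–Hochberg correction, purity–VAF correlations, and a
feature-vs-estimator Spearman screen).

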