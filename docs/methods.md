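# Methods

## The analysis

`prsoverlap` measures shared genetic background between a *base* trait, for
which only GWAS summary statistics are available, and a *target*
case/control cohort with individual-level genotypes. The workflow is the
classic clumping-and-thresholding (C+T) polygenic-score analysis:

1. **Genotype QC.** SNPs with call rate < 0.95, Hardy-Weinberg
   disequilibrium p < 1e-6 (1-df chi-square goodness of fit against the
   frequencies implied by the sample allele frequency), or minor allele
   frequency < 0.01 are removed; samples with call rate < 0.95 or
   heterozygosity outside mean ± 3 SD are removed. All thresholds are strict
   inequalities; boundary values survive. The filters run in the order
   SNP call rate → sample call rate → HWE → MAF → heterozygosity, each stage
   recomputing its statistics on the current matrix. The order is a package
   convention (any fixed order is reproducible; the report records it).
   The heterozygosity mean/SD (ddof = 1) are computed once over all samples,
   with no iteration after removals.
2. **Base GWAS** (when base genotypes rather than published summary
   statistics are supplied): one logistic regression per SNP, dosage coded
   additively, missing dosages mean-imputed per SNP, Wald p-values, and a
   Bonferroni column `min(1, p·M)` with `M` the number of SNPs actually
   tested (monomorphic SNPs are skipped and logged).
3. **Harmonization.** Summary-statistic effects are aligned to the target
   genotypes' counted allele: identical allele pairs keep the sign (flipped
   when the effect allele is the non-counted allele), pairs matching only
   under reverse complement are used after a strand flip, palindromic
   (A/T, C/G) SNPs are dropped in strict mode, everything else is dropped
   with logged counts.
4. **LD clumping.** Greedy, p-value-ordered (ties: position, then id): each
   retained index SNP removes all not-yet-retained SNPs within ±250 kb on
   the same chromosome whose dosage r² with it exceeds 0.1. A pure
   position-ordered pruning mode exists for comparison. Clumping runs once,
   before the threshold scan.
5. **PRS.** For sample *j* over the included SNP set,
   `PRS_j = (Σ_i S_i·G_ij) / M_j`, where `S_i` is the harmonized per-allele
   log-odds effect, `G_ij` the effect-allele dosage, and `M_j` the number of
   alleles included for that sample — 2 per non-missing included SNP, so
   missing genotypes shrink both numerator and denominator. Samples with no
   typed included SNP get a missing score.
6. **Threshold scan.** Source-p thresholds run from 1e-4 in steps of 5e-5 up
   to 0.5 (the upper bound is a package default; start and increment are the
   analysis convention this package follows, the stop is configurable). At
   each threshold the PRS includes clump survivors with source p strictly
   below it; thresholds whose SNP set is empty or unchanged carry the
   previous result forward. The fit at each threshold is
   `logit P(case) = β₀ + β₁·PRS` (plus optional covariates); explained
   variance is the Nagelkerke pseudo-R²
   `R²_N = [1 − exp((2/n)(ℓ₀ − ℓ₁))] / [1 − exp((2/n)ℓ₀)]`
   (Cox–Snell available via a flag) and the association p is the Wald test
   on β₁ (likelihood-ratio via a flag). The best threshold maximizes R²_N,
   ties going to the smaller threshold. The best-threshold p is reported
   nominally; an empirical label-permutation p is *not* applied by default
   because the reference analysis convention reports the nominal value —
   users should remember the scan maximizes over thresholds.
7. **Pathway enrichment.** Overlap SNPs (by default those included at the
   best threshold; optionally all clump survivors) are mapped to every gene
   whose interval ± flank (default 50 kb, configurable) contains them. A
   gene's score is the sum of 1-df chi-square deviates of its SNPs'
   p-values. A set's statistic is the mean score of its scored members
   (sum via a flag — mean keeps unequal set sizes comparable); its null is
   `n_perm` same-size draws without replacement from all scored genes; the
   empirical p is `(1 + #{null ≥ observed})/(1 + n_perm)`, never below
   `1/(n_perm+1)`. Ties are counted with a 1e-9 relative tolerance so a set
   equal to the whole universe gets p = 1 despite float summation order.
   Set p-values are Benjamini–Hochberg adjusted and binned at FDR
   1% / 5% / 10% / 15%. This gene scoring is a deliberate simplification of
   full LD-corrected pathway scoring: the resampling null absorbs the
   score-scale inflation that LD causes, but the null matches set size only,
   not gene length or SNP count (SNP-count matching is a documented
   extension point).

### Logistic fitting

The fitter is Fisher-scored IRLS, converging when every score component is
below 1e-8 (at most 100 iterations), with Wald p-values from the expected
information. Rank-deficient designs and single-class outcomes raise;
complete separation (fitted probabilities saturated on both classes) is
flagged as non-converged rather than silently returned. The covariate-free
per-SNP GWAS and the threshold scan use a batched two-parameter Newton
kernel (numba-jitted with a numpy fallback) that the test suite pins to the
generic fitter at 1e-8; coefficients additionally match statsmodels'
independent Newton MLE to 1e-6 on random designs.

## The synthetic-data generator

The generator emulates the discovery/replication design the pipeline is
meant for: two cohorts drawn from one SNP panel, a binary phenotype per
cohort, and a tunable causal overlap.

* **Genotypes.** Two independent haplotypes per sample; each is a latent
  Gaussian AR(1) process within fixed-size blocks (Gaussian copula), an
  allele being minor when its latent value is below the MAF quantile. This
  keeps every SNP exactly at Hardy-Weinberg while giving precise control of
  the within-block r² decay the clumping stage needs; blocks are mutually
  independent. SNPs sit one per kb on a single chromosome, so a 250 kb
  window spans 250 SNPs. The latent draws use float32 (plenty for a copula
  threshold; halves the simulation's memory traffic).
* **Effects.** Causal sets are drawn without replacement; the target set
  shares `shared_fraction` of its SNPs with the base set, and shared SNPs
  carry the *same* raw normal effect in both traits (trait-private SNPs get
  independent draws), so the liability-scale genetic correlation tracks the
  shared fraction — with independent values the correlation would be ~0 and
  there would be nothing to detect. Per-trait effects are rescaled so
  `Σ 2f(1−f)β²` equals the requested h². Effect magnitudes are i.i.d.
  normal with equal variance (no frequency dependence).
* **Phenotypes.** Liability = √h² · (standardized true genetic score) +
  √(1−h²) · N(0,1); case iff liability exceeds the normal (1−prevalence)
  quantile. No intermediate-pain category is modelled: only the
  case/control dichotomy enters the analysis, so generating the underlying
  0–10 pain scores would add nothing testable.
* **QC fixtures.** `inject_qc_violations` corrupts disjoint SNP/sample sets
  per rule (missingness for call rate, a het-free MAF-0.5 column for HWE, a
  single heterozygote for MAF, an all-heterozygous sample for the
  heterozygosity filter) and returns an exact manifest, so QC removal lists
  can be compared to ground truth count-for-count.
* **Annotation.** Genes tile half the genome span with equal gaps; gene
  sets are uniform draws, except an optional positive-control set loaded
  with genes containing causal SNPs. When the true effect sizes are passed,
  the positive control takes the *strongest* causal genes — with normal
  effects the heritability concentrates in a few SNPs, and a random causal
  subset that misses the dominant gene is not a reliable positive control.

### Study conditions (generator defaults)

5000 SNPs in 25-SNP blocks (latent rho = 0.7), MAF uniform on (0.05, 0.5),
50 causal SNPs per trait (causal_fraction = 0.01), liability h² = 0.3 per
trait, prevalence 0.5 in both cohorts (balanced case/control sampling, the
regime in which a logistic target analysis is best behaved), base n = 2000,
target n = 600. These were fixed by a design-stage power argument: 50 causal
SNPs at h² = 0.3 give a per-SNP observed-scale R² ≈ 0.004 and a base-GWAS
non-centrality ≈ 7.6 at n = 2000, enough for the C+T score to carry most of
the signal, while the target association at n = 600 then has high power;
with a disjoint causal architecture the two traits' effect draws are
independent, so LD leakage between the sets has zero expected correlation
and the nominal test stays calibrated.

### What the generator does not emulate

Realistic human LD maps (block AR(1) only), allele-frequency-dependent
architectures, imputation uncertainty, population structure/relatedness,
covariate effects, X chromosome, indels/multiallelics, genotyping batch
effects. Passing recovery tests therefore shows the *machinery* is correct
under its stated model, not that real-cohort effect sizes would reproduce.

## Numerical choices

* Threshold grid membership uses strict `p < t`, grid inclusion `t ≤ stop`
  within 1e-12.
* The PRS numerator is accumulated SNP-by-SNP left to right so scores are
  bit-reproducible against a naive per-sample evaluation (no BLAS pairwise
  reordering).
* Clumping treats monomorphic columns (undefined r²) as unlinked.
* `maf` filtering keeps all-missing SNPs for the call-rate rule to flag.
* Tie-breaks everywhere: ascending p, then position, then lexicographic id.
* One master seed; per-stage streams are derived via `SeedSequence` with
  fixed stage tags, so toggling a stage never shifts another stage's draws;
  identical config+seed reruns are byte-identical (the run report's
  wall-clock field aside).

## Problem sizes used in the checks

The acceptance-style experiments run the full study conditions with 200
replicates per arm in the test suite (60 per arm in
`scripts/acceptance.py`, whose numbers are rates and means over those
replicates); the pathway positive-control study uses 1000 SNPs / n = 1200 /
50 sets with 2000 permutations. These sizes were chosen so the full suite
completes comfortably on a single CPU while leaving the binomial/KS
acceptance bands meaningful.

## Known limitations

* The nominal best-threshold p is optimistic under the null because it
  maximizes over the grid (the calibration experiment therefore tests at a
  fixed threshold); the optional permutation p exists but is off by
  default, mirroring the reference convention.
* The pathway null matches set size only; sets whose genes are
  systematically longer (more SNPs) than average inherit a mild bias that
  the uniform-set calibration cannot see.
* The HWE test is the 1-df chi-square, not the exact test — at very small
  genotype counts the exact test would differ; computed on all samples, not
  controls only.
* `M_j` counts alleles (2 per non-missing SNP). Counting SNPs instead would
  only rescale every score by 2 and cannot change any association.
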