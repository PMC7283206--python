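# prsoverlap

Polygenic-risk-score analysis of **shared genetic background** between a
chronic-pain (or any case/control) trait with published GWAS summary
statistics and a target cohort with individual-level genotypes — for
example, testing whether chronic postsurgical pain patients carry an excess
of risk alleles identified for other peripheral pain syndromes. The package
is aimed at statistical geneticists who want the standard
clumping-and-thresholding (C+T) workflow as a tested, scriptable library
with a synthetic-cohort generator that makes every stage verifiable by
parameter recovery.

## What it computes

Given base-trait summary statistics *S* and target genotypes *G*, the score
of individual *j* over an included SNP set is the additive PRS

```
PRS_j = ( Σ_i  S_i · G_ij ) / M_j
```

with `S_i` the per-allele log-odds for the effect allele of SNP *i*,
`G_ij` the number of effect alleles carried, and `M_j` the number of
alleles included for that individual (2 per non-missing SNP). SNPs are
first LD-clumped (greedy by ascending p; remove r² > 0.1 within 250 kb),
then scored at source-p thresholds from 1e-4 in steps of 5e-5; at each
threshold a logistic regression `status ~ PRS` yields Nagelkerke's

```
R²_N = [1 − exp((2/n)(ℓ₀ − ℓ₁))] / [1 − exp((2/n) ℓ₀)]
```

and a Wald p; the best threshold maximizes R²_N. Around this core sit
genotype QC with the standard strict filters (SNP/sample call rate < 0.95,
HWE p < 1e-6, MAF < 0.01, heterozygosity ± 3 SD), a per-SNP logistic GWAS
with Bonferroni correction, allele harmonization (strand flips, palindrome
handling), and permutation-based gene-set enrichment with BH-FDR binning at
1/5/10/15%. `docs/methods.md` has the full model description.

## Worked example

Simulate a base cohort (n = 2000) and an independent target cohort
(n = 600) whose traits share **all** causal variants, run the base GWAS,
and scan thresholds against the target phenotype:

```python
from prsoverlap import assoc, prscore, synthdata

cfg = synthdata.SimulationConfig(shared_fraction=1.0, seed=7)
cohorts = synthdata.simulate_cohorts(cfg)

sumstats = assoc.gwas(cohorts.base, cohorts.pheno_base)
scan = prscore.scan_thresholds(sumstats, cohorts.target, cohorts.pheno_target,
                               strict_palindromic=False)
print(f"best threshold {scan.best_threshold:g}: "
      f"R2={scan.best_r2:.4f} p={scan.best_p:.3g} ({scan.best_n_snps} SNPs)")
```

which prints

```
best threshold 0.00015: R2=0.1963 p=1.37e-18 (10 SNPs)
```

i.e. the scan settles on the source-p cutoff 1.5e-4, where a 10-SNP score
explains ~20% of the target case/control variance (Nagelkerke) with an
overwhelming association — the genetic overlap put into the simulation is
recovered. Rerunning with `shared_fraction=0.0` gives an R² near zero and
a non-significant p.

The same pipeline runs from the shell on VCF/TSV/BED/GMT inputs:

```bash
prsoverlap simulate --out sim/ --seed 7
prsoverlap qc   --vcf sim/target.vcf --out sim/target_qc.vcf
prsoverlap gwas --vcf sim/base.vcf --pheno sim/pheno_base.tsv --out sim/ss.tsv
prsoverlap prs  --sumstats sim/ss.tsv --vcf sim/target_qc.vcf \
                --pheno sim/pheno_target.tsv --out sim/scan.tsv
prsoverlap run-all --config config.yaml        # whole pipeline + report
prsoverlap compare --scan-a a/scan.tsv --scan-b b/scan.tsv   # two cohorts
```

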