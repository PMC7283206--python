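"""Genotype quality control with auditable removal lists.

Filters and thresholds (all strict inequalities, boundary values retained):

* SNP call rate < 0.95
* sample (subject) call rate < 0.95
* Hardy-Weinberg equilibrium p < 1e-6 (1-df chi-square goodness of fit)
* minor allele frequency < 0.01
* sample heterozygosity outside mean +/- 3 SD

``run_qc`` applies them in that order, recomputing every statistic on the
current matrix, and reports per-rule removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .dataio import GenotypeMatrix

RULE_SNP_CALL_RATE = "snp_call_rate"
RULE_SAMPLE_CALL_RATE = "sample_call_rate"
RULE_HWE = "hwe"
RULE_MAF = "maf"
RULE_HET = "heterozygosity"

RULE_ORDER = [RULE_SNP_CALL_RATE, RULE_SAMPLE_CALL_RATE, RULE_HWE, RULE_MAF, RULE_HET]


@dataclass
class QcParams:
    snp_call_rate: float = 0.95
    sample_call_rate: float = 0.95
    hwe_alpha: float = 1e-6
    maf: float = 0.01
    het_sd: float = 3.0


@dataclass
class QcReport:
    removed_snps_by_rule: dict[str, list[str]] = field(default_factory=dict)
    removed_samples_by_rule: dict[str, list[str]] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    order: list[str] = field(default_factory=lambda: list(RULE_ORDER))

    @property
    def n_removed_snps(self) -> int:
        return sum(len(v) for v in self.removed_snps_by_rule.values())

    @property
    def n_removed_samples(self) -> int:
        return sum(len(v) for v in self.removed_samples_by_rule.values())


def _check_nonempty(g: GenotypeMatrix) -> None:
    if g.n_samples == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")


def snp_call_rates(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per SNP."""
    _check_nonempty(g)
    return 1.0 - np.isnan(g.dosage).mean(axis=0)


def sample_call_rates(g: GenotypeMatrix) -> np.ndarray:
    _check_nonempty(g)
    return 1.0 - np.isnan(g.dosage).mean(axis=1)


def filter_snp_call_rate(g: GenotypeMatrix, threshold: float = 0.95):
    """Remove SNPs with call rate strictly below ``threshold``."""
    keep = snp_call_rates(g) >= threshold
    removed = g.snps.loc[~keep, "id"].tolist()
    return g.take_snps(np.flatnonzero(keep)), removed


def filter_sample_call_rate(g: GenotypeMatrix, threshold: float = 0.95):
    keep = sample_call_rates(g) >= threshold
    removed = [sid for sid, k in zip(g.sample_ids, keep) if not k]
    return g.take_samples(np.flatnonzero(keep)), removed


def hwe_test(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Genotype counts are (a1/a1, a1/a2, a2/a2). Monomorphic SNPs get p = 1.
    """
    counts = np.array([n_hom_a1, n_het, n_hom_a2], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    stat = float(np.sum((counts - expected) ** 2 / expected))
    return float(chi2.sf(stat, df=1))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    _check_nonempty(g)
    d = g.dosage
    n2 = np.nansum(d == 2, axis=0)
    n1 = np.nansum(d == 1, axis=0)
    n0 = np.nansum(d == 0, axis=0)
    return np.array([hwe_test(a, b, c) for a, b, c in zip(n2, n1, n0)])


def filter_hwe(g: GenotypeMatrix, alpha: float = 1e-6):
    """Remove SNPs whose HWE p-value is strictly below ``alpha``."""
    keep = hwe_pvalues(g) >= alpha
    removed = g.snps.loc[~keep, "id"].tolist()
    return g.take_snps(np.flatnonzero(keep)), removed


def minor_allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP MAF from non-missing dosages; NaN for all-missing SNPs."""
    _check_nonempty(g)
    with np.errstate(invalid="ignore"):
        f = np.nanmean(g.dosage, axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def filter_maf(g: GenotypeMatrix, threshold: float = 0.01):
    maf = minor_allele_frequencies(g)
    keep = ~(maf < threshold)  # NaN (all-missing) survives to the call-rate rule
    removed = g.snps.loc[~keep, "id"].tolist()
    return g.take_snps(np.flatnonzero(keep)), removed


def heterozygosity_rates(g: GenotypeMatrix) -> np.ndarray:
    """Per-sample fraction of heterozygous calls among non-missing calls."""
    _check_nonempty(g)
    het = (g.dosage == 1).sum(axis=1)
    nonmiss = (~np.isnan(g.dosage)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(nonmiss > 0, het / nonmiss, np.nan)


def filter_heterozygosity(g: GenotypeMatrix, k: float = 3.0):
    """Remove samples with heterozygosity outside mean +/- k*SD.

    Mean and SD (ddof=1) are computed over all samples in a single pass;
    boundary values are retained. SD of zero removes nobody.
    """
    if g.n_samples < 2:
        raise ValueError("heterozygosity filter needs at least 2 samples")
    het = heterozygosity_rates(g)
    mean = np.nanmean(het)
    sd = np.nanstd(het, ddof=1)
    if not np.isfinite(sd) or sd == 0 or not np.isfinite(k):
        keep = np.ones(g.n_samples, dtype=bool)
    else:
        keep = np.abs(het - mean) <= k * sd
        keep |= np.isnan(het)
    removed = [sid for sid, kk in zip(g.sample_ids, keep) if not kk]
    return g.take_samples(np.flatnonzero(keep)), removed


def run_qc(g: GenotypeMatrix, params: QcParams | None = None):
    """Apply all filters in the fixed order, recomputing at each stage.

    Order: SNP call rate -> sample call rate -> HWE -> MAF -> heterozygosity.
    Returns (filtered matrix, QcReport).
    """
    params = params or QcParams()
    report = QcReport(
        thresholds={
            RULE_SNP_CALL_RATE: params.snp_call_rate,
            RULE_SAMPLE_CALL_RATE: params.sample_call_rate,
            RULE_HWE: params.hwe_alpha,
            RULE_MAF: params.maf,
            RULE_HET: params.het_sd,
        }
    )
    g, removed = filter_snp_call_rate(g, params.snp_call_rate)
    report.removed_snps_by_rule[RULE_SNP_CALL_RATE] = removed
    g, removed = filter_sample_call_rate(g, params.sample_call_rate)
    report.removed_samples_by_rule[RULE_SAMPLE_CALL_RATE] = removed
    g, removed = filter_hwe(g, params.hwe_alpha)
    report.removed_snps_by_rule[RULE_HWE] = removed
    g, removed = filter_maf(g, params.maf)
    report.removed_snps_by_rule[RULE_MAF] = removed
    g, removed = filter_heterozygosity(g, params.het_sd)
    report.removed_samples_by_rule[RULE_HET] = removed
    return g, report
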