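"""Synthetic base/target cohort generator for PRS genetic-overlap experiments.

The generator emulates the discovery/replication design of a PRS overlap
study: a "base" cohort whose case/control GWAS supplies summary statistics,
and an independent "target" cohort whose binary phenotype shares a
controllable fraction of causal variants with the base trait.

Model
-----
* Genotypes: Hardy-Weinberg draws with block-wise LD. Each of the two
  haplotypes per sample is generated from a latent Gaussian AR(1) process
  within fixed-size blocks (Gaussian copula); an allele is the minor allele
  when its latent value falls below the MAF quantile. Blocks are mutually
  independent; SNPs sit one per kb on a single chromosome so a 250 kb
  clumping window spans 250 SNPs.
* Effects: causal SNP sets are drawn without replacement per trait; the
  target causal set shares ``shared_fraction`` of its SNPs with the base set.
  Effect sizes are i.i.d. normal, scaled so the per-SNP variance
  contributions ``2 f (1-f) beta^2`` sum to the requested liability-scale
  heritability.
* Phenotypes: liability-threshold model. Liability is the standardized
  genetic score times sqrt(h2) plus Gaussian noise of variance 1-h2; a
  sample is a case when liability exceeds the normal (1-prevalence)
  quantile.

All operations are pure functions of (inputs, seed); the same seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataio import GenotypeMatrix

_BASE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]

# sub-stream tags so toggling one draw never shifts another stream
_STREAM_MAF = 101
_STREAM_GENO = 102
_STREAM_EFFECTS = 103
_STREAM_PHENO_BASE = 104
_STREAM_PHENO_TARGET = 105
_STREAM_QC = 106
_STREAM_GENES = 107


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic base/target experiment.

    Defaults are the conditions used throughout the package's recovery
    experiments: 5000 SNPs in 25-SNP LD blocks (latent AR(1) rho = 0.7),
    50 causal SNPs per trait (causal_fraction = 0.01), liability h2 = 0.3 for
    both traits, balanced case/control sampling (prevalence 0.5), base
    n = 2000 and target n = 600.
    """

    n_snps: int = 5000
    block_size: int = 25
    rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_base: int = 2000
    n_target: int = 600
    causal_fraction: float = 0.01
    shared_fraction: float = 1.0
    h2_base: float = 0.3
    h2_target: float = 0.3
    prevalence_base: float = 0.5
    prevalence_target: float = 0.5
    snp_spacing_bp: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_snps <= 0 or self.block_size <= 0:
            raise ValueError("n_snps and block_size must be positive")
        if self.n_base <= 0 or self.n_target <= 0:
            raise ValueError("sample counts must be positive")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("causal_fraction", "shared_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("h2_base", "h2_target"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("prevalence_base", "prevalence_target"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class EffectAssignment:
    """True per-SNP liability-scale effects and causal index sets."""

    beta_base: np.ndarray
    beta_target: np.ndarray
    causal_base: np.ndarray
    causal_target: np.ndarray

    @property
    def n_shared(self) -> int:
        return len(np.intersect1d(self.causal_base, self.causal_target))


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), stream]))


def draw_mafs(config: SimulationConfig) -> np.ndarray:
    """Per-SNP minor-allele frequencies, uniform over ``maf_range``."""
    rng = _rng(config.seed, _STREAM_MAF)
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_snps)


def simulate_genotypes(config: SimulationConfig, n_samples: int | None = None) -> GenotypeMatrix:
    """Simulate HWE genotypes with AR(1) block LD on the latent scale.

    By default generates ``n_base + n_target`` samples (base cohort first);
    split with :meth:`GenotypeMatrix.take_samples`.
    """
    n = int(n_samples) if n_samples is not None else config.n_base + config.n_target
    if n <= 0:
        raise ValueError("number of samples must be positive")
    m = config.n_snps
    mafs = draw_mafs(config)
    thresholds = norm.ppf(mafs)  # latent < threshold -> minor allele

    rng = _rng(config.seed, _STREAM_GENO)
    scale = np.sqrt(1.0 - config.rho**2)
    bs = config.block_size
    m_pad = ((m + bs - 1) // bs) * bs  # last block may be short; pad and trim
    rho32 = np.float32(config.rho)
    scale32 = np.float32(scale)
    thr32 = thresholds.astype(np.float32)
    counts = np.zeros((n, m), dtype=np.uint8)
    for _hap in range(2):
        # float32 latent scale: plenty for a copula threshold at these MAFs
        e = rng.standard_normal((n, m), dtype=np.float32)
        if m_pad != m:
            e = np.concatenate([e, np.zeros((n, m_pad - m), dtype=np.float32)], axis=1)
        z = e.reshape(n, m_pad // bs, bs)
        # AR(1) recursion vectorized over all blocks at once
        for k in range(1, bs):
            z[:, :, k] = rho32 * z[:, :, k - 1] + scale32 * z[:, :, k]
        counts += z.reshape(n, m_pad)[:, :m] < thr32
    dosage = counts.astype(float)

    alleles = [_BASE_PAIRS[i % len(_BASE_PAIRS)] for i in range(m)]
    snps = pd.DataFrame(
        {
            "id": [f"snp{i + 1:06d}" for i in range(m)],
            "chrom": "1",
            "pos": 1 + np.arange(m) * config.snp_spacing_bp,
            "a1": [a for a, _ in alleles],
            "a2": [b for _, b in alleles],
        }
    )
    sample_ids = [f"S{j + 1:05d}" for j in range(n)]
    return GenotypeMatrix(sample_ids=sample_ids, snps=snps, dosage=dosage)


def draw_effects(config: SimulationConfig) -> EffectAssignment:
    """Draw causal sets and liability-scale effect sizes for both traits."""
    rng = _rng(config.seed, _STREAM_EFFECTS)
    m = config.n_snps
    n_causal = int(round(config.causal_fraction * m))
    n_shared = int(round(config.shared_fraction * n_causal))
    if n_shared > n_causal:
        raise ValueError("shared_fraction demands more shared SNPs than the causal set holds")

    causal_base = np.sort(rng.choice(m, size=n_causal, replace=False))
    shared = np.sort(rng.choice(causal_base, size=n_shared, replace=False)) \
        if n_shared else np.array([], dtype=int)
    pool = np.setdiff1d(np.arange(m), causal_base)
    n_extra = n_causal - n_shared
    if n_extra > len(pool):
        raise ValueError("not enough non-base-causal SNPs for a disjoint target set")
    extra = np.sort(rng.choice(pool, size=n_extra, replace=False)) \
        if n_extra else np.array([], dtype=int)
    causal_target = np.sort(np.concatenate([shared, extra])).astype(int)

    mafs = draw_mafs(config)

    def _scale(beta_raw: np.ndarray, h2: float) -> np.ndarray:
        idx = np.flatnonzero(beta_raw)
        beta = np.zeros(m)
        if len(idx) == 0 or h2 == 0:
            return beta
        var = 2.0 * mafs[idx] * (1.0 - mafs[idx])
        total = float(np.sum(var * beta_raw[idx] ** 2))
        beta[idx] = beta_raw[idx] * np.sqrt(h2 / total)
        return beta

    # shared causal SNPs carry the same raw effect in both traits, so the
    # genetic correlation tracks shared_fraction; trait-private causal SNPs
    # get independent draws
    raw_base = np.zeros(m)
    raw_base[causal_base] = rng.standard_normal(n_causal)
    raw_target = np.zeros(m)
    raw_target[shared] = raw_base[shared]
    raw_target[extra] = rng.standard_normal(n_extra)

    beta_base = _scale(raw_base, config.h2_base)
    beta_target = _scale(raw_target, config.h2_target)
    return EffectAssignment(beta_base, beta_target, causal_base.astype(int), causal_target)


def simulate_phenotypes(
    g: GenotypeMatrix, effects: np.ndarray, h2: float, prevalence: float, seed: int
) -> pd.DataFrame:
    """Liability-threshold binary phenotypes.

    Returns a phenotype table with sample_id, status (case/control) and the
    latent liability (kept so heritability recovery is checkable).
    """
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (g.n_snps,):
        raise ValueError("effect vector length must equal the SNP count")
    if not 0 <= h2 < 1:
        raise ValueError("h2 must lie in [0, 1)")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    gs = g.dosage @ effects
    sd = gs.std()
    noise = rng.standard_normal(g.n_samples)
    if h2 == 0 or sd == 0:
        liability = noise
    else:
        liability = np.sqrt(h2) * (gs - gs.mean()) / sd + np.sqrt(1.0 - h2) * noise
    threshold = norm.ppf(1.0 - prevalence)
    status = np.where(liability > threshold, "case", "control")
    return pd.DataFrame(
        {"sample_id": g.sample_ids, "status": status, "liability": liability}
    )


def simulate_cohorts(config: SimulationConfig) -> SimpleNamespace:
    """Generate the full experiment: shared SNP panel, base + target cohorts,
    true effects, and liability-threshold phenotypes for both."""
    g_all = simulate_genotypes(config)
    base = g_all.take_samples(np.arange(config.n_base))
    target = g_all.take_samples(np.arange(config.n_base, config.n_base + config.n_target))
    # re-label target samples so the two cohorts have disjoint id spaces
    target.sample_ids = [f"T{j + 1:05d}" for j in range(config.n_target)]
    effects = draw_effects(config)
    seed_b = int(np.random.SeedSequence([config.seed, _STREAM_PHENO_BASE]).generate_state(1)[0] % (2**31))
    seed_t = int(np.random.SeedSequence([config.seed, _STREAM_PHENO_TARGET]).generate_state(1)[0] % (2**31))
    pheno_base = simulate_phenotypes(
        base, effects.beta_base, config.h2_base, config.prevalence_base, seed_b
    )
    pheno_target = simulate_phenotypes(
        target, effects.beta_target, config.h2_target, config.prevalence_target, seed_t
    )
    return SimpleNamespace(
        base=base, target=target, effects=effects,
        pheno_base=pheno_base, pheno_target=pheno_target, config=config,
    )


# ---------------------------------------------------------------------------
# QC-violation fixtures
# ---------------------------------------------------------------------------

@dataclass
class QcViolationSpec:
    """How many SNPs/samples to corrupt per QC rule."""

    n_snp_low_call: int = 0
    n_snp_hwe: int = 0
    n_snp_low_maf: int = 0
    n_sample_low_call: int = 0
    n_sample_het_outlier: int = 0
    snp_missing_fraction: float = 0.10  # per corrupted SNP / sample
    sample_missing_fraction: float = 0.10


def inject_qc_violations(
    g: GenotypeMatrix, spec: QcViolationSpec, seed: int
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Corrupt disjoint SNP/sample subsets so each QC rule fires on a known set.

    Returns the corrupted matrix and a manifest mapping rule name to the ids
    deliberately pushed past that rule's threshold. Sample corruptions are
    applied before SNP-column corruptions so the SNP-level manifests are exact.
    """
    n, m = g.n_samples, g.n_snps
    n_bad_snps = spec.n_snp_low_call + spec.n_snp_hwe + spec.n_snp_low_maf
    n_bad_samples = spec.n_sample_low_call + spec.n_sample_het_outlier
    if n_bad_snps > m:
        raise ValueError("requested more corrupted SNPs than the matrix holds")
    if n_bad_samples > n:
        raise ValueError("requested more corrupted samples than the matrix holds")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_QC]))
    dosage = g.dosage.copy()
    snp_idx = rng.choice(m, size=n_bad_snps, replace=False)
    lc_snps = snp_idx[: spec.n_snp_low_call]
    hwe_snps = snp_idx[spec.n_snp_low_call: spec.n_snp_low_call + spec.n_snp_hwe]
    maf_snps = snp_idx[spec.n_snp_low_call + spec.n_snp_hwe:]
    sample_idx = rng.choice(n, size=n_bad_samples, replace=False)
    lc_samples = sample_idx[: spec.n_sample_low_call]
    het_samples = sample_idx[spec.n_sample_low_call:]
    clean_snps = np.setdiff1d(np.arange(m), snp_idx)

    # samples first ------------------------------------------------------
    n_miss_per_sample = max(int(np.ceil(spec.sample_missing_fraction * m)), int(0.05 * m) + 1)
    if n_miss_per_sample > len(clean_snps):
        raise ValueError("sample call-rate corruption would overlap corrupted SNP columns")
    for j in lc_samples:
        cols = rng.choice(clean_snps, size=n_miss_per_sample, replace=False)
        dosage[j, cols] = np.nan
    for j in het_samples:
        dosage[j, :] = 1.0  # heterozygous everywhere: het rate 1.0

    # SNP columns --------------------------------------------------------
    n_miss_per_snp = max(int(np.ceil(spec.snp_missing_fraction * n)), int(0.05 * n) + 1)
    for i in lc_snps:
        rows = rng.choice(n, size=n_miss_per_snp, replace=False)
        dosage[rows, i] = np.nan
    for i in hwe_snps:
        # no heterozygotes at MAF 0.5: chi-square = n, far past p < 1e-6
        col = np.zeros(n)
        col[rng.permutation(n)[: n // 2]] = 2.0
        dosage[:, i] = col
    for i in maf_snps:
        col = np.zeros(n)
        col[rng.integers(n)] = 1.0  # single het: MAF = 1/(2n) < 0.01 for n >= 51
        dosage[:, i] = col

    manifest = {
        "snp_call_rate": [g.snps["id"].iloc[i] for i in lc_snps],
        "hwe": [g.snps["id"].iloc[i] for i in hwe_snps],
        "maf": [g.snps["id"].iloc[i] for i in maf_snps],
        "sample_call_rate": [g.sample_ids[j] for j in lc_samples],
        "heterozygosity": [g.sample_ids[j] for j in het_samples],
    }
    out = GenotypeMatrix(sample_ids=list(g.sample_ids), snps=g.snps.copy(), dosage=dosage)
    return out, manifest


# ---------------------------------------------------------------------------
# gene annotation and gene sets
# ---------------------------------------------------------------------------

def simulate_gene_annotation(
    n_genes: int,
    genome_span: int,
    seed: int,
    n_sets: int = 0,
    set_size: int = 10,
    causal_positions: np.ndarray | None = None,
    causal_weights: np.ndarray | None = None,
    enriched: bool = False,
    enrich_fraction: float = 0.8,
    chrom: str = "1",
) -> SimpleNamespace:
    """Tile non-overlapping genes along one chromosome and draw gene sets.

    Genes occupy half the span (equal-width bodies separated by equal gaps).
    With ``enriched`` set, the first gene set ("ENRICHED") is loaded with
    genes whose bodies contain a causal SNP position (at least
    ``enrich_fraction`` of its members); remaining sets are uniform draws.
    When ``causal_weights`` (e.g. |true effect| per causal position) are
    given, the loaded genes are the strongest causal genes rather than a
    random subset, making the set a proper positive control. Returns genes
    (BED-convention frame), sets dict, and a manifest with the causal-gene
    list.
    """
    if n_genes == 0:
        genes = pd.DataFrame(columns=["chrom", "start", "end", "gene_id", "pos_start", "pos_end"])
        return SimpleNamespace(genes=genes, sets={}, manifest={"causal_genes": []})
    if n_genes < 0 or genome_span <= 0:
        raise ValueError("n_genes and genome_span must be non-negative/positive")
    pitch = genome_span // n_genes
    gene_len = pitch // 2
    if gene_len < 1:
        raise ValueError(f"{n_genes} genes cannot fit in a span of {genome_span} bp")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_GENES]))
    starts = np.arange(n_genes) * pitch
    genes = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + gene_len,
            "gene_id": [f"GENE{i + 1:04d}" for i in range(n_genes)],
        }
    )
    genes["pos_start"] = genes["start"] + 1
    genes["pos_end"] = genes["end"]

    causal_genes: list[str] = []
    gene_weight: dict[str, float] = {}
    if causal_positions is not None and len(causal_positions):
        pos = np.asarray(causal_positions)
        hit = (pos[None, :] >= genes["pos_start"].to_numpy()[:, None]) & (
            pos[None, :] <= genes["pos_end"].to_numpy()[:, None]
        )
        causal_genes = genes.loc[hit.any(axis=1), "gene_id"].tolist()
        if causal_weights is not None:
            w = np.abs(np.asarray(causal_weights, dtype=float))
            for gi in np.flatnonzero(hit.any(axis=1)):
                gene_weight[genes["gene_id"].iat[gi]] = float(w[hit[gi]].max())

    sets: dict[str, list[str]] = {}
    all_ids = genes["gene_id"].tolist()
    if n_sets:
        if set_size > n_genes:
            raise ValueError("set_size exceeds the number of genes")
        start_k = 0
        if enriched:
            n_loaded = int(np.ceil(enrich_fraction * set_size))
            if n_loaded > len(causal_genes):
                raise ValueError(
                    f"enriched set needs {n_loaded} causal genes but only "
                    f"{len(causal_genes)} genes contain a causal SNP"
                )
            if gene_weight:
                ranked = sorted(causal_genes, key=lambda gid: -gene_weight[gid])
                loaded = ranked[:n_loaded]
            else:
                loaded = list(rng.choice(causal_genes, size=n_loaded, replace=False))
            others = [gid for gid in all_ids if gid not in loaded]
            filler = list(rng.choice(others, size=set_size - n_loaded, replace=False))
            sets["ENRICHED"] = loaded + filler
            start_k = 1
        for k in range(start_k, n_sets):
            sets[f"SET{k + 1:04d}"] = list(rng.choice(all_ids, size=set_size, replace=False))
    return SimpleNamespace(
        genes=genes, sets=sets, manifest={"causal_genes": causal_genes}
    )
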