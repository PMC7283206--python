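"""Readers and writers for the on-disk formats the pipeline touches.

Dialect contracts
-----------------
* VCF and summary statistics are 1-based; BED is 0-based half-open. All
  in-memory positions are 1-based.
* Genotype dosages count copies of the **a1** (effect/ALT) allele and live in
  {0, 1, 2}; missing genotypes are ``NaN`` — never silently imputed at read
  time.
* Summary-statistic effect sizes are per-allele log-odds (an ``OR`` column is
  converted to ``beta = ln(OR)`` on read).
* Tab-delimited outputs may start with ``#``-prefixed provenance comments;
  every reader here skips them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical summary-statistics column order on disk
SUMSTAT_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p"]

#: default mapping from on-disk header names to canonical names
DEFAULT_SUMSTAT_COLUMN_MAP = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "BP": "pos",
    "A1": "effect_allele",
    "A2": "other_allele",
    "BETA": "beta",
    "OR": "odds_ratio",
    "P": "p",
}


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNV; ``a1`` is the counted (effect) allele."""

    id: str
    chrom: str
    pos: int  # 1-based
    a1: str
    a2: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.a1, self.a2):
            if allele not in _BASES:
                raise ValueError(f"allele {allele!r} is not a single-base SNV allele")


@dataclass
class GenotypeMatrix:
    """samples x SNPs additive dosage matrix with SNP metadata.

    ``dosage[j, i]`` is the number of copies of ``snps.a1[i]`` carried by
    sample ``j`` (float, ``NaN`` = missing call).
    """

    sample_ids: list[str]
    snps: pd.DataFrame  # columns: id, chrom, pos, a1, a2
    dosage: np.ndarray  # (n_samples, n_snps) float

    def __post_init__(self):
        self.snps = self.snps.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        d = self.dosage
        if d.size > 4_000_000:  # spot-check large matrices on a fixed stride
            d = d.reshape(-1)[::17]
        vals = d[~np.isnan(d)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0,1,2} or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=self.snps.iloc[index],
            dosage=self.dosage[:, index],
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            snps=self.snps.copy(),
            dosage=self.dosage[index, :],
        )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read tab-delimited GWAS summary statistics into canonical form.

    Requires header columns mapping to snp_id/chrom/pos/effect_allele/
    other_allele/p and one of beta or odds_ratio. Rows with p outside (0, 1],
    missing or non-SNV alleles, or effect_allele == other_allele are dropped
    (count logged).
    """
    cmap = dict(DEFAULT_SUMSTAT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df = df.rename(columns={k: v for k, v in cmap.items() if k in df.columns})
    needed = {"snp_id", "chrom", "pos", "effect_allele", "other_allele", "p"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics missing mandatory columns: {sorted(missing)}")
    if "beta" not in df.columns and "odds_ratio" not in df.columns:
        raise ValueError("summary statistics need a BETA or OR column")

    try:
        df["pos"] = df["pos"].astype(int)
        df["p"] = df["p"].astype(float)
        if "beta" in df.columns:
            df["beta"] = df["beta"].astype(float)
        else:
            df["beta"] = np.log(df["odds_ratio"].astype(float))
    except ValueError as exc:
        raise ValueError(f"unparseable numeric field in summary statistics: {exc}") from exc

    n0 = len(df)
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    ok = (
        df["p"].gt(0)
        & df["p"].le(1)
        & df["beta"].notna()
        & ea.isin(sorted(_BASES))
        & oa.isin(sorted(_BASES))
        & (ea != oa)
    )
    dropped = int(n0 - ok.sum())
    if dropped:
        log.info("read_summary_stats: dropped %d/%d malformed rows", dropped, n0)
    df = df.loc[ok].copy()
    df["effect_allele"] = ea[ok]
    df["other_allele"] = oa[ok]
    df["chrom"] = df["chrom"].astype(str)
    df["snp_id"] = df["snp_id"].astype(str)
    df.attrs["n_dropped"] = dropped
    return df[SUMSTAT_COLUMNS].reset_index(drop=True)


def write_summary_stats(df: pd.DataFrame, path, header_comments: list[str] | None = None) -> None:
    """Write canonical summary statistics as a PLINK-style TSV (SNP/CHR/BP/A1/A2/BETA/P)."""
    out = df[SUMSTAT_COLUMNS].rename(
        columns={
            "snp_id": "SNP", "chrom": "CHR", "pos": "BP",
            "effect_allele": "A1", "other_allele": "A2", "beta": "BETA", "p": "P",
        }
    )
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_genotypes(path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix of ALT-allele dosages (a1 = ALT).

    GT 0/0, 0/1, 1/1 map to 0, 1, 2; missing GT maps to NaN. When GT is
    absent, DS is used, rounded to the nearest integer clipped to [0, 2].
    Multiallelic and non-SNV records are skipped (count logged).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} has no samples")
    rows, meta, skipped = [], [], 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1 \
                or v.REF not in _BASES or v.ALT[0] not in _BASES:
            skipped += 1
            continue
        dos = np.full(len(samples), np.nan)
        try:
            gts = v.genotypes  # [[a, b, phased], ...]
        except Exception:
            gts = None  # record without GT
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        have_gt = gts is not None and any(
            a is not None and a >= 0 for g in gts for a in g[:-1]
        )
        if gts is None and ds is None:
            skipped += 1
            continue
        if have_gt or ds is None:
            for j, g in enumerate(gts):
                alleles = g[:-1]
                if any(a is None or a < 0 for a in alleles):
                    continue
                dos[j] = float(sum(alleles))
        else:
            ds = np.asarray(ds, dtype=float).reshape(len(samples))
            with np.errstate(invalid="ignore"):
                dos = np.clip(np.rint(ds), 0, 2)
        rows.append(dos)
        meta.append((v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), int(v.POS), v.ALT[0], v.REF))
    vcf.close()
    if skipped:
        log.info("read_vcf_genotypes: skipped %d non-biallelic/non-SNV records", skipped)
    snps = pd.DataFrame(meta, columns=["id", "chrom", "pos", "a1", "a2"])
    dosage = np.array(rows).T if rows else np.empty((len(samples), 0))
    g = GenotypeMatrix(sample_ids=samples, snps=snps, dosage=dosage)
    return g


def write_vcf_genotypes(g: GenotypeMatrix, path, extra_header: list[str] | None = None) -> None:
    """Write GT-only VCF 4.2; REF = a2, ALT = a1 (the counted allele)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in extra_header or []:
            fh.write(f"##{line}\n")
        for chrom in pd.unique(g.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        order = np.lexsort((g.snps["pos"].to_numpy(), g.snps["chrom"].to_numpy()))
        for i in order:
            s = g.snps.iloc[i]
            gts = "\t".join(
                gt_map.get(d, "./.") if not np.isnan(d) else "./." for d in g.dosage[:, i]
            )
            fh.write(f"{s.chrom}\t{s.pos}\t{s.id}\t{s.a2}\t{s.a1}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

VALID_STATUS = {"case", "control", "excluded"}


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV: sample_id, optional nrs (0-10), optional status,
    remaining columns treated as numeric covariates."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("phenotype table must have a sample_id column")
    if "nrs" in df.columns:
        df["nrs"] = df["nrs"].astype("Int64")
        bad = df["nrs"].dropna()
        if ((bad < 0) | (bad > 10)).any():
            raise ValueError("nrs values must lie in 0..10")
    if "status" in df.columns:
        unknown = set(df["status"].dropna()) - VALID_STATUS
        if unknown:
            raise ValueError(f"unknown status values: {sorted(unknown)}")
    for col in df.columns:
        if col not in ("sample_id", "nrs", "status"):
            df[col] = df[col].astype(float)
    return df


def write_phenotypes(df: pd.DataFrame, path, header_comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# genes (BED4) and gene sets (GMT)
# ---------------------------------------------------------------------------

def read_bed_genes(path) -> pd.DataFrame:
    """Read BED4 gene intervals (0-based half-open) into a frame with both
    conventions: start/end as in the file, pos_start/pos_end 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "start": int, "end": int, "gene_id": str},
    )
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "gene_id"].tolist()
        raise ValueError(f"BED intervals with start >= end: {bad}")
    df["pos_start"] = df["start"] + 1
    df["pos_end"] = df["end"]
    return df


def write_bed_genes(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "gene_id"]].to_csv(path, sep="\t", index=False, header=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: name<TAB>description<TAB>member genes. Members are
    deduplicated preserving order; empty sets are rejected."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line with no members: {parts[0]!r}")
            name, members = parts[0], [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"empty gene set {name!r}")
            sets[name] = list(dict.fromkeys(members))
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description] + list(members)) + "\n")
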