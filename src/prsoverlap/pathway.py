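"""Gene-level scoring of overlap SNPs and permutation gene-set enrichment.

A gene's score is the sum over its mapped SNPs of the 1-df chi-square
deviates corresponding to their p-values. A gene set's enrichment statistic
is the mean score of its scored members, assessed against a null built by
repeatedly drawing the same number of scored genes uniformly without
replacement; the empirical p is (1 + #{null >= observed}) / (1 + n_perm).
Set-level p-values are Benjamini-Hochberg adjusted and binned at FDR
1/5/10/15%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

FDR_BINS = ((0.01, "<1%"), (0.05, "<=5%"), (0.10, "<=10%"), (0.15, "<=15%"))

#: tolerance used when counting null draws >= observed, so that exact ties
#: (e.g. the set equal to the whole universe) are counted despite float
#: summation order
_TIE_TOL = 1e-9


@dataclass
class PathwayResult:
    name: str
    observed: float
    n_scored: int
    p_empirical: float
    q: float | None = None
    fdr_bin: str | None = None


def map_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 50_000
) -> dict[str, list[str]]:
    """Assign each SNP to every gene whose flanked interval contains it.

    ``snps`` needs snp_id/chrom/pos (1-based); ``genes`` needs
    gene_id/chrom/pos_start/pos_end (1-based inclusive, as produced by
    :func:`prsoverlap.dataio.read_bed_genes`). SNPs mapping to no gene are
    dropped (count logged). Returns gene_id -> list of SNP ids.
    """
    trees: dict[str, IntervalTree] = {}
    for r in genes.itertuples(index=False):
        lo = max(1, int(r.pos_start) - flank_bp)
        hi = int(r.pos_end) + flank_bp
        trees.setdefault(str(r.chrom), IntervalTree()).addi(lo, hi + 1, r.gene_id)

    mapping: dict[str, list[str]] = {}
    unmapped = 0
    for r in snps.itertuples(index=False):
        tree = trees.get(str(r.chrom))
        hits = tree[int(r.pos)] if tree is not None else ()
        if not hits:
            unmapped += 1
            continue
        for h in hits:
            mapping.setdefault(h.data, []).append(r.snp_id)
    if unmapped:
        log.info("map_snps_to_genes: %d SNPs mapped to no gene", unmapped)
    return mapping


def gene_score(p_values) -> float:
    """Sum of upper-tail 1-df chi-square deviates for one gene's SNP p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("gene has no SNP p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.sum(chi2.isf(p, df=1)))


def score_genes(
    sumstats: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 50_000
) -> pd.DataFrame:
    """Chi-square sum scores for every gene with at least one mapped SNP."""
    mapping = map_snps_to_genes(sumstats, genes, flank_bp=flank_bp)
    pmap = sumstats.set_index("snp_id")["p"]
    rows = [
        (gid, gene_score(pmap.loc[snp_ids].to_numpy()), len(snp_ids))
        for gid, snp_ids in mapping.items()
    ]
    return pd.DataFrame(rows, columns=["gene_id", "score", "n_snps"])


def pathway_enrichment(
    gene_scores: pd.Series | pd.DataFrame,
    gene_set: list[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    stat: str = "mean",
    name: str = "",
) -> PathwayResult:
    """Permutation enrichment of one gene set against random same-size draws.

    ``gene_scores`` is a Series indexed by gene id (or the frame from
    :func:`score_genes`). The null resamples sets of the same size from all
    scored genes, matching set size only.
    """
    if isinstance(gene_scores, pd.DataFrame):
        gene_scores = gene_scores.set_index("gene_id")["score"]
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    scored = [gid for gid in dict.fromkeys(gene_set) if gid in gene_scores.index]
    if not scored:
        raise ValueError("no gene in the set has a score")
    if len(scored) > len(gene_scores):
        raise ValueError("set size exceeds the number of scored genes")
    values = gene_scores.to_numpy(dtype=float)
    s = len(scored)
    agg = np.mean if stat == "mean" else np.sum
    if stat not in ("mean", "sum"):
        raise ValueError(f"unknown statistic {stat!r}")
    observed = float(agg(gene_scores.loc[scored].to_numpy()))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # s smallest random keys per row = a uniform draw without replacement
    keys = rng.random((n_perm, len(values)))
    idx = np.argpartition(keys, s - 1, axis=1)[:, :s]
    null = agg(values[idx], axis=1)
    tol = _TIE_TOL * max(1.0, abs(observed))
    n_ge = int(np.sum(null >= observed - tol))
    p = (1.0 + n_ge) / (1.0 + n_perm)
    return PathwayResult(name=name, observed=observed, n_scored=s, p_empirical=p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_fdr_bins(q_values) -> list[str]:
    """Bin q-values at the 1/5/10/15% FDR levels ('ns' above 15%)."""
    out = []
    for q in np.asarray(q_values, dtype=float):
        for cut, label in FDR_BINS:
            if q <= cut:
                out.append(label)
                break
        else:
            out.append("ns")
    return out


def pathway_analysis(
    gene_scores: pd.DataFrame | pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 10_000,
    seed: int = 0,
    stat: str = "mean",
) -> pd.DataFrame:
    """Enrichment of every gene set, with BH-FDR q-values and FDR bins.

    Deterministic given ``seed``: each set gets an independent child stream
    in input order.
    """
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    streams = np.random.SeedSequence(seed).spawn(len(gene_sets))
    rows = []
    for ss, (name, members) in zip(streams, gene_sets.items()):
        try:
            res = pathway_enrichment(
                gene_scores, members, n_perm=n_perm,
                seed=np.random.default_rng(ss), stat=stat, name=name,
            )
        except ValueError:
            # no member gene carries a score: unscorable, not an error for
            # the batch table
            rows.append((name, np.nan, 0, np.nan))
            continue
        rows.append((name, res.observed, res.n_scored, res.p_empirical))
    df = pd.DataFrame(rows, columns=["set", "score", "n_scored", "p"])
    if df["p"].notna().sum() == 0:
        raise ValueError("no gene set has any scored gene")
    q = np.full(len(df), np.nan)
    ok = df["p"].notna().to_numpy()
    q[ok] = bh_fdr(df.loc[ok, "p"].to_numpy())
    df["q"] = q
    df["fdr_bin"] = [b if np.isfinite(qq) else "ns"
                     for qq, b in zip(q, assign_fdr_bins(np.nan_to_num(q, nan=1.0)))]
    return df
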