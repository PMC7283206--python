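"""Clumping-and-thresholding polygenic risk scores.

The additive PRS for sample j over an included SNP set is

    PRS_j = ( sum_i S_i * G_ij ) / M_j

where S_i is the harmonized per-allele effect (log-odds) of SNP i, G_ij the
number of effect alleles sample j carries, and M_j the number of alleles
included for that sample (2 per non-missing included SNP). SNP selection is
greedy p-value-ordered clumping (remove neighbours with r^2 > 0.1 within a
250 kb window), followed by a scan over source p-value thresholds starting
at 1e-4 in steps of 5e-5; the best threshold maximizes Nagelkerke R^2 of the
PRS-phenotype logistic fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import assoc
from .dataio import COMPLEMENT, GenotypeMatrix

log = logging.getLogger(__name__)

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class PruneConfig:
    r2_threshold: float = 0.1
    window_bp: int = 250_000
    mode: str = "clump_by_p"  # or "position_prune"

    def __post_init__(self):
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in (0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.mode not in ("clump_by_p", "position_prune"):
            raise ValueError(f"unknown prune mode {self.mode!r}")


@dataclass
class PrsVector:
    """Per-sample score and included-allele count at one threshold."""

    sample_ids: list[str]
    score: np.ndarray
    m_alleles: np.ndarray
    threshold: float | None
    snp_ids: list[str]


@dataclass
class ScanResult:
    """Threshold grid with per-threshold SNP count, explained variance and p."""

    thresholds: np.ndarray
    n_snps: np.ndarray
    r2: np.ndarray
    p: np.ndarray
    best_index: int
    snp_ids_by_p: list[str] = field(default_factory=list)  # clump survivors, ascending p

    @property
    def best_threshold(self) -> float:
        return float(self.thresholds[self.best_index])

    @property
    def best_r2(self) -> float:
        return float(self.r2[self.best_index])

    @property
    def best_p(self) -> float:
        return float(self.p[self.best_index])

    @property
    def best_n_snps(self) -> int:
        return int(self.n_snps[self.best_index])

    def best_snp_ids(self) -> list[str]:
        return self.snp_ids_by_p[: self.best_n_snps]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"threshold": self.thresholds, "n_snps": self.n_snps, "r2": self.r2, "p": self.p}
        )
        df["best"] = 0
        df.loc[self.best_index, "best"] = 1
        return df


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize(
    sumstats: pd.DataFrame, g: GenotypeMatrix, strict_palindromic: bool = True
) -> pd.DataFrame:
    """Align summary-statistic effects to the genotype matrix's counted allele.

    Match by SNP id, then resolve alleles: identical pair keeps the sign
    (flipped when the effect allele is the genotype's a2), a pair matching
    only under reverse complement is treated after a strand flip, palindromic
    (A/T, C/G) SNPs are dropped in strict mode, anything else is dropped.
    Returns a frame with genotype column index ``col``, aligned ``beta`` and
    source ``p``; drop counts are logged and stored in ``.attrs``.
    """
    if len(sumstats) == 0 or g.n_snps == 0:
        raise ValueError("empty summary statistics or genotype matrix")
    geno = g.snps.reset_index(drop=True).reset_index(names="col")
    merged = sumstats.merge(geno, left_on="snp_id", right_on="id", how="inner",
                            suffixes=("", "_g"))
    drops = {"unmatched": len(sumstats) - len(merged), "palindromic": 0, "mismatch": 0}
    rows = []
    for r in merged.itertuples(index=False):
        ea, oa, a1, a2 = r.effect_allele, r.other_allele, r.a1, r.a2
        if strict_palindromic and (ea, oa) in _PALINDROMIC:
            drops["palindromic"] += 1
            continue
        if {ea, oa} == {a1, a2}:
            sign = 1.0 if ea == a1 else -1.0
        elif {COMPLEMENT[ea], COMPLEMENT[oa]} == {a1, a2}:
            sign = 1.0 if COMPLEMENT[ea] == a1 else -1.0
        else:
            drops["mismatch"] += 1
            continue
        rows.append((r.col, r.snp_id, r.chrom_g, r.pos_g, sign * r.beta, r.p))
    out = pd.DataFrame(rows, columns=["col", "snp_id", "chrom", "pos", "beta", "p"])
    if drops["unmatched"] or drops["palindromic"] or drops["mismatch"]:
        log.info("harmonize: dropped %s", drops)
    if len(out) == 0:
        raise ValueError("zero SNPs matched between summary statistics and genotypes")
    out.attrs["drops"] = drops
    return out


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(g: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns over jointly
    non-missing samples."""
    a, b = g.dosage[:, i], g.dosage[:, j]
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 jointly observed samples")
    a, b = a[mask], b[mask]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero dosage variance in jointly observed samples")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _visit_order(harm: pd.DataFrame, mode: str) -> np.ndarray:
    ids = harm["snp_id"].to_numpy()
    pos = harm["pos"].to_numpy()
    if mode == "clump_by_p":
        return np.lexsort((ids, pos, harm["p"].to_numpy()))
    return np.lexsort((ids, pos))


def clump(harm: pd.DataFrame, g: GenotypeMatrix, cfg: PruneConfig | None = None) -> np.ndarray:
    """Greedy LD clumping of harmonized SNPs.

    Visits SNPs by ascending source p (ties by position then id; pure
    position order in ``position_prune`` mode). Each visited SNP that has not
    been removed is retained and removes every not-yet-retained SNP on the
    same chromosome within ±window_bp whose r^2 with it exceeds the
    threshold. Returns retained row indices into ``harm`` (ascending p order).
    Monomorphic columns have undefined r^2 and are treated as unlinked.
    """
    cfg = cfg or PruneConfig()
    if len(harm) == 0:
        raise ValueError("empty harmonized input")
    order = _visit_order(harm, cfg.mode)
    pos = harm["pos"].to_numpy()
    chrom = harm["chrom"].to_numpy()
    cols = harm["col"].to_numpy()

    d = g.dosage[:, cols]
    has_missing = bool(np.isnan(d).any())
    if not has_missing:
        sd = d.std(axis=0)
        safe = np.where(sd == 0, 1.0, sd)
        z = (d - d.mean(axis=0)) / safe
        z[:, sd == 0] = 0.0  # monomorphic: correlates with nothing
        n = d.shape[0]

    removed = np.zeros(len(harm), dtype=bool)
    retained_mask = np.zeros(len(harm), dtype=bool)
    retained = []
    for k in order:
        if removed[k]:
            continue
        retained.append(k)
        retained_mask[k] = True
        near = (
            (chrom == chrom[k])
            & (np.abs(pos - pos[k]) <= cfg.window_bp)
            & ~removed
            & ~retained_mask
        )
        cand = np.flatnonzero(near)
        if cand.size == 0:
            continue
        if has_missing:
            for j in cand:
                try:
                    r2 = ld_r2(g, cols[k], cols[j])
                except ValueError:
                    continue
                if r2 > cfg.r2_threshold:
                    removed[j] = True
        else:
            r = z[:, cand].T @ z[:, k] / n
            removed[cand[r * r > cfg.r2_threshold]] = True
    return np.asarray(retained, dtype=int)


# ---------------------------------------------------------------------------
# the PRS equation
# ---------------------------------------------------------------------------

def compute_prs(
    g: GenotypeMatrix, harm: pd.DataFrame, included: np.ndarray, threshold: float | None = None
) -> PrsVector:
    """Additive PRS over the included harmonized rows.

    PRS_j = sum_i S_i G_ij / M_j with M_j = 2 x (included SNPs non-missing in
    sample j); samples with M_j = 0 get a missing (NaN) score.
    """
    included = np.asarray(included, dtype=int)
    if included.size == 0:
        raise ValueError("empty included SNP set")
    sub = harm.iloc[included]
    w = sub["beta"].to_numpy()
    d = g.dosage[:, sub["col"].to_numpy()]
    nonmiss = ~np.isnan(d)
    # accumulate SNP by SNP (left to right) so the floating-point sum is
    # reproducible and bit-identical to a naive per-sample evaluation
    num = np.zeros(g.n_samples)
    for i in range(len(sub)):
        num += np.where(nonmiss[:, i], d[:, i], 0.0) * w[i]
    m = 2 * nonmiss.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(m > 0, num / np.where(m == 0, 1, m), np.nan)
    return PrsVector(
        sample_ids=list(g.sample_ids), score=score, m_alleles=m,
        threshold=threshold, snp_ids=sub["snp_id"].tolist(),
    )


def threshold_grid(start: float = 1e-4, step: float = 5e-5, stop: float = 0.5) -> np.ndarray:
    """Arithmetic p-value threshold grid: start, start+step, ... <= stop
    (inclusive within 1e-12)."""
    if start <= 0 or step <= 0:
        raise ValueError("start and step must be positive")
    if stop < start:
        raise ValueError("stop must be >= start")
    n = int(np.floor((stop - start) / step + 1e-9))
    while start + (n + 1) * step <= stop + 1e-12:
        n += 1
    while n > 0 and start + n * step > stop + 1e-12:
        n -= 1
    return start + np.arange(n + 1) * step


# ---------------------------------------------------------------------------
# threshold scan
# ---------------------------------------------------------------------------

def scan_clumped(
    harm: pd.DataFrame,
    clumped: np.ndarray,
    g: GenotypeMatrix,
    phen: pd.DataFrame,
    grid: np.ndarray | None = None,
    covariates: list[str] | None = None,
) -> ScanResult:
    """Threshold scan over an already-clumped SNP set.

    For each grid threshold the PRS includes clump survivors with source
    p < threshold; thresholds whose SNP set is empty or unchanged carry the
    previous result forward. Best = maximal Nagelkerke R^2, ties to the
    smaller threshold.
    """
    grid = threshold_grid() if grid is None else np.asarray(grid, dtype=float)
    sub = harm.iloc[np.asarray(clumped, dtype=int)]
    order = np.lexsort((sub["snp_id"].to_numpy(), sub["pos"].to_numpy(), sub["p"].to_numpy()))
    sub = sub.iloc[order].reset_index(drop=True)
    ps = sub["p"].to_numpy()
    counts = np.searchsorted(ps, grid, side="left")  # strict p < t
    if counts.max() == 0:
        raise ValueError("no threshold on the grid includes any SNP")

    y_all = assoc._status_to_binary(phen)
    sample_in = np.array([sid in y_all.index for sid in g.sample_ids])
    d = g.dosage[np.flatnonzero(sample_in), :][:, sub["col"].to_numpy()]
    y = y_all.loc[[sid for sid, ok in zip(g.sample_ids, sample_in) if ok]].to_numpy()
    if len(y) < 10 or y.min() == y.max():
        raise ValueError("need >= 10 overlapping samples with both classes")

    w = sub["beta"].to_numpy()
    nonmiss = ~np.isnan(d)
    num_cum = np.cumsum(np.where(nonmiss, d, 0.0) * w[None, :], axis=1)
    m_cum = 2 * np.cumsum(nonmiss, axis=1)

    distinct = np.unique(counts[counts > 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(
            m_cum[:, distinct - 1] > 0,
            num_cum[:, distinct - 1] / np.where(m_cum[:, distinct - 1] == 0, 1,
                                                m_cum[:, distinct - 1]),
            np.nan,
        )

    n = len(y)
    ll_null = (
        assoc.logistic_fit(np.column_stack([np.ones(n)] + (
            [phen.set_index("sample_id").loc[
                [sid for sid, ok in zip(g.sample_ids, sample_in) if ok], covariates
            ].to_numpy(dtype=float)] if covariates else [])), y).loglik
        if covariates else assoc.intercept_only_loglik(y)
    )

    r2_by_k = {}
    p_by_k = {}
    if covariates or np.isnan(scores).any():
        # general path: one explicit fit per distinct SNP set
        for col_i, k in enumerate(distinct):
            prs = PrsVector(
                sample_ids=[sid for sid, ok in zip(g.sample_ids, sample_in) if ok],
                score=scores[:, col_i], m_alleles=m_cum[:, k - 1],
                threshold=None, snp_ids=sub["snp_id"].tolist()[:k],
            )
            res = assoc.prs_association(prs, phen, covariates=covariates)
            r2_by_k[k] = res.r2_nagelkerke
            p_by_k[k] = res.p_value
    else:
        if np.ptp(scores, axis=0).min() == 0:
            const = np.ptp(scores, axis=0) == 0
            for k in distinct[const]:
                r2_by_k[int(k)] = 0.0
                p_by_k[int(k)] = 1.0
            keep = ~const
        else:
            keep = np.ones(len(distinct), dtype=bool)
        if keep.any():
            _, b1, se1, ll, _ = assoc.batch_logistic_slope(scores[:, keep], y)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = b1 / se1
            pw = 2.0 * norm.sf(np.abs(z))
            r2v = np.array([assoc.nagelkerke_r2(ll_null, max(l, ll_null), n) for l in ll])
            for k, r2k, pk in zip(distinct[keep], r2v, pw):
                r2_by_k[int(k)] = float(r2k)
                p_by_k[int(k)] = float(pk)

    r2 = np.full(len(grid), np.nan)
    p = np.full(len(grid), np.nan)
    for t_i, k in enumerate(counts):
        if k > 0:
            r2[t_i] = r2_by_k[int(k)]
            p[t_i] = p_by_k[int(k)]
    best = int(np.nanargmax(r2))
    # ties: np.nanargmax already returns the first (smallest threshold)
    return ScanResult(
        thresholds=grid, n_snps=counts.astype(int), r2=r2, p=p,
        best_index=best, snp_ids_by_p=sub["snp_id"].tolist(),
    )


def scan_thresholds(
    sumstats: pd.DataFrame,
    g: GenotypeMatrix,
    phen: pd.DataFrame,
    prune: PruneConfig | None = None,
    grid: np.ndarray | None = None,
    strict_palindromic: bool = True,
    covariates: list[str] | None = None,
) -> ScanResult:
    """Full clumping-and-thresholding scan: harmonize once, clump once, then
    scan the p-value threshold grid."""
    harm = harmonize(sumstats, g, strict_palindromic=strict_palindromic)
    clumped = clump(harm, g, prune)
    return scan_clumped(harm, clumped, g, phen, grid=grid, covariates=covariates)
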