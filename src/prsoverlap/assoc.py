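"""Logistic-regression machinery: per-SNP GWAS, PRS-phenotype association,
and Nagelkerke explained variance.

The maximum-likelihood fitter is a Fisher-scored IRLS written here (the
generic path) plus a batched two-parameter Newton kernel used for the
covariate-free per-SNP GWAS and the threshold scan, where thousands of
intercept+slope models must be fitted. Both converge on
``max |score| < 1e-8`` or 100 iterations and report Wald p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, chi2

from .dataio import GenotypeMatrix

log = logging.getLogger(__name__)

MAX_ITER = 100
SCORE_TOL = 1e-8

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco


@dataclass
class LogisticFit:
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    converged: bool
    p_values: np.ndarray

    def wald_p(self, index: int) -> float:
        return float(self.p_values[index])


@dataclass
class AssociationResult:
    """PRS-phenotype association summary."""

    r2_nagelkerke: float
    p_value: float
    threshold: float | None
    n_snps: int
    beta: float
    n: int


def dichotomize_phenotype(nrs: int) -> str:
    """Map a 0-10 numeric rating scale pain score to analysis status:
    0 -> control, >3 -> case, 1-3 -> excluded."""
    nrs = int(nrs)
    if not 0 <= nrs <= 10:
        raise ValueError(f"NRS score must lie in 0..10, got {nrs}")
    if nrs == 0:
        return "control"
    if nrs > 3:
        return "case"
    return "excluded"


def logistic_fit(X: np.ndarray, y: np.ndarray,
                 max_iter: int = MAX_ITER, tol: float = SCORE_TOL) -> LogisticFit:
    """Fisher-scored IRLS logistic regression.

    Raises on a single-class outcome or a rank-deficient design; complete
    separation surfaces as ``converged=False`` rather than a silent result.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design matrix and outcome are misaligned")
    n, p = X.shape
    if n == 0:
        raise ValueError("empty design")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient (collinear columns)")

    beta = np.zeros(p)
    converged = False
    H = np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        score = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            beta = beta + np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break

    eta = X @ beta
    mu = np.clip(expit(eta), 1e-300, 1 - 1e-16)
    loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    # complete separation: fitted probabilities saturate on both classes;
    # the score still vanishes, so flag rather than return a silent "fit"
    if converged and mu[y == 1].min() > 1 - 1e-6 and mu[y == 0].max() < 1e-6:
        converged = False
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * norm.sf(np.abs(z))
    return LogisticFit(coef=beta, se=se, loglik=loglik, n=n,
                       converged=converged, p_values=pvals)


@njit(cache=True)
def _batch_logit_kernel(x, y, base_intercept, max_iter, tol):  # pragma: no cover - numba
    n, m = x.shape
    b0 = np.zeros(m)
    b1 = np.zeros(m)
    se1 = np.zeros(m)
    ll = np.zeros(m)
    conv = np.zeros(m, dtype=np.bool_)
    for j in range(m):
        a0 = base_intercept
        a1 = 0.0
        ok = False
        for _ in range(max_iter):
            g0 = 0.0
            g1 = 0.0
            h00 = 0.0
            h01 = 0.0
            h11 = 0.0
            for i in range(n):
                xi = x[i, j]
                e = a0 + a1 * xi
                muij = 1.0 / (1.0 + np.exp(-e))
                w = muij * (1.0 - muij)
                r = y[i] - muij
                g0 += r
                g1 += r * xi
                h00 += w
                h01 += w * xi
                h11 += w * xi * xi
            if abs(g0) < tol and abs(g1) < tol:
                ok = True
                break  # h00/h01/h11 already hold the converged information
            det = h00 * h11 - h01 * h01
            if det <= 0.0 or not np.isfinite(det):
                break
            a0 += (h11 * g0 - h01 * g1) / det
            a1 += (-h01 * g0 + h00 * g1) / det
        llj = 0.0
        for i in range(n):
            e = a0 + a1 * x[i, j]
            if e > 35.0:
                e = 35.0
            elif e < -35.0:
                e = -35.0
            if y[i] > 0.5:
                llj += -np.log1p(np.exp(-e))
            else:
                llj += -np.log1p(np.exp(e))
        det = h00 * h11 - h01 * h01
        if det > 0.0:
            se1[j] = np.sqrt(h00 / det)
        else:
            se1[j] = np.nan
        b0[j] = a0
        b1[j] = a1
        ll[j] = llj
        conv[j] = ok
    return b0, b1, se1, ll, conv


def _batch_logit_numpy(x, y, base_intercept, max_iter, tol):
    """Vectorized fallback for the batched intercept+slope logistic fits."""
    n, m = x.shape
    b0 = np.full(m, base_intercept)
    b1 = np.zeros(m)
    conv = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        eta = b0[None, :] + x * b1[None, :]
        mu = expit(eta)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (r * x).sum(axis=0)
        newly = (np.abs(g0) < tol) & (np.abs(g1) < tol)
        conv |= newly
        if conv.all():
            break
        w = mu * (1.0 - mu)
        h00 = w.sum(axis=0)
        h01 = (w * x).sum(axis=0)
        h11 = (w * x * x).sum(axis=0)
        det = h00 * h11 - h01 * h01
        ok = ~conv & (det > 0) & np.isfinite(det)
        b0 = np.where(ok, b0 + (h11 * g0 - h01 * g1) / np.where(det == 0, 1, det), b0)
        b1 = np.where(ok, b1 + (-h01 * g0 + h00 * g1) / np.where(det == 0, 1, det), b1)
    eta = b0[None, :] + x * b1[None, :]
    mu = np.clip(expit(eta), 1e-300, 1 - 1e-16)
    ll = (y[:, None] * np.log(mu) + (1 - y[:, None]) * np.log1p(-mu)).sum(axis=0)
    w = mu * (1.0 - mu)
    h00 = w.sum(axis=0)
    h01 = (w * x).sum(axis=0)
    h11 = (w * x * x).sum(axis=0)
    det = h00 * h11 - h01 * h01
    with np.errstate(invalid="ignore", divide="ignore"):
        se1 = np.where(det > 0, np.sqrt(h00 / np.where(det <= 0, 1, det)), np.nan)
    return b0, b1, se1, ll, conv


def batch_logistic_slope(x: np.ndarray, y: np.ndarray):
    """Fit ``logit P(y=1) = b0 + b1 * x[:, j]`` for every column j at once.

    Returns (b0, b1, se1, loglik, converged) arrays. Same convergence rule as
    :func:`logistic_fit`; results agree with it to well below 1e-6.
    """
    x = np.ascontiguousarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    if ybar <= 0 or ybar >= 1:
        raise ValueError("outcome has a single class")
    base = float(np.log(ybar / (1.0 - ybar)))
    if _HAVE_NUMBA:
        return _batch_logit_kernel(x, y, base, MAX_ITER, SCORE_TOL)
    return _batch_logit_numpy(x, y, base, MAX_ITER, SCORE_TOL)


def intercept_only_loglik(y: np.ndarray) -> float:
    """Closed-form log-likelihood of the intercept-only logistic model."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = y.sum()
    ll = 0.0
    if 0 < k:
        ll += k * np.log(k / n)
    if k < n:
        ll += (n - k) * np.log((n - k) / n)
    return float(ll)


def nagelkerke_r2(ll_null: float, ll_full: float, n: int, kind: str = "nagelkerke") -> float:
    """Pseudo explained variance of a logistic model.

    Cox-Snell: R2_CS = 1 - exp((2/n)(ll_null - ll_full)); Nagelkerke rescales
    by the maximum attainable 1 - exp((2/n) ll_null) so the range is [0, 1].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if ll_full < ll_null - 1e-9:
        raise ValueError("full-model log-likelihood is below the null's")
    ll_full = max(ll_full, ll_null)
    r2_cs = 1.0 - np.exp((2.0 / n) * (ll_null - ll_full))
    if kind == "coxsnell":
        return float(np.clip(r2_cs, 0.0, 1.0))
    if kind != "nagelkerke":
        raise ValueError(f"unknown pseudo-R2 kind {kind!r}")
    denom = 1.0 - np.exp((2.0 / n) * ll_null)
    if denom <= 0:
        return 0.0
    return float(np.clip(r2_cs / denom, 0.0, 1.0))


def _status_to_binary(phen: pd.DataFrame) -> pd.Series:
    if "status" not in phen.columns:
        raise ValueError("phenotype table has no status column")
    st = phen.set_index("sample_id")["status"]
    st = st[st.isin(["case", "control"])]
    return (st == "case").astype(float)


def gwas(
    g: GenotypeMatrix,
    phen: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP additive logistic GWAS with a Bonferroni-adjusted p column.

    Samples with status 'excluded' are dropped; missing dosages are
    mean-imputed per SNP for the fit; monomorphic SNPs are skipped (logged).
    ``p_bonf = min(1, p * M)`` with M the number of SNPs actually tested.
    """
    y_all = _status_to_binary(phen)
    idx = [j for j, sid in enumerate(g.sample_ids) if sid in y_all.index]
    if not idx:
        raise ValueError("no samples shared between genotypes and phenotypes")
    y = y_all.loc[[g.sample_ids[j] for j in idx]].to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome has a single class after alignment")
    if len(idx) == g.n_samples:
        d = g.dosage  # only copied below if imputation must write into it
    else:
        d = g.dosage[idx, :]

    # per-SNP mean imputation of missing dosages
    miss = np.isnan(d)
    if miss.any():
        d = d.copy()
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        d[miss] = np.take(col_mean, np.nonzero(miss)[1])
        log.info("gwas: mean-imputed %d missing dosage cells", int(miss.sum()))

    poly = d.std(axis=0) > 0
    n_mono = int((~poly).sum())
    if n_mono:
        log.info("gwas: skipped %d monomorphic SNPs", n_mono)
    cols = np.flatnonzero(poly)
    if cols.size == 0:
        raise ValueError("zero polymorphic SNPs after alignment")

    if covariates:
        cov = phen.set_index("sample_id").loc[
            [g.sample_ids[j] for j in idx], covariates
        ].to_numpy(dtype=float)
        betas, ses, pvals = [], [], []
        for c in cols:
            X = np.column_stack([np.ones(len(y)), cov, d[:, c]])
            fit = logistic_fit(X, y)
            betas.append(fit.coef[-1])
            ses.append(fit.se[-1])
            pvals.append(fit.p_values[-1])
        beta, se, p = np.array(betas), np.array(ses), np.array(pvals)
    else:
        x = d if cols.size == d.shape[1] else d[:, cols]
        _, beta, se, _, _ = batch_logistic_slope(x, y)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta / se
        p = 2.0 * norm.sf(np.abs(z))

    m_tested = cols.size
    out = pd.DataFrame(
        {
            "snp_id": g.snps["id"].to_numpy()[cols],
            "chrom": g.snps["chrom"].to_numpy()[cols],
            "pos": g.snps["pos"].to_numpy()[cols],
            "effect_allele": g.snps["a1"].to_numpy()[cols],
            "other_allele": g.snps["a2"].to_numpy()[cols],
            "beta": beta,
            "se": se,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
        }
    )
    out["p_bonf"] = np.minimum(1.0, out["p"] * m_tested)
    out.attrs["n_tested"] = m_tested
    out.attrs["n_monomorphic"] = n_mono
    return out


def prs_association(
    prs,
    phen: pd.DataFrame,
    covariates: list[str] | None = None,
    test: str = "wald",
    r2_kind: str = "nagelkerke",
) -> AssociationResult:
    """Association of a PRS with case/control status.

    Full model: intercept + covariates + PRS; null: intercept + covariates.
    R2 is the Nagelkerke increment of full over null; p is the Wald test on
    the PRS coefficient (``test='lrt'`` switches to a likelihood ratio test).
    """
    y_all = _status_to_binary(phen)
    score = pd.Series(prs.score, index=prs.sample_ids).dropna()
    shared = [s for s in score.index if s in y_all.index]
    if len(shared) < 10:
        raise ValueError("fewer than 10 samples shared between PRS and phenotype")
    y = y_all.loc[shared].to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome has a single class in the overlap")
    x = score.loc[shared].to_numpy()
    n = len(y)

    cov = np.empty((n, 0))
    if covariates:
        cov = phen.set_index("sample_id").loc[shared, covariates].to_numpy(dtype=float)

    if np.ptp(x) == 0:  # constant PRS carries no information
        return AssociationResult(
            r2_nagelkerke=0.0, p_value=1.0, threshold=getattr(prs, "threshold", None),
            n_snps=len(getattr(prs, "snp_ids", [])), beta=0.0, n=n,
        )

    X_null = np.column_stack([np.ones(n), cov])
    X_full = np.column_stack([X_null, x])
    if cov.shape[1]:
        ll_null = logistic_fit(X_null, y).loglik
    else:
        ll_null = intercept_only_loglik(y)
    fit = logistic_fit(X_full, y)
    r2 = nagelkerke_r2(ll_null, fit.loglik, n, kind=r2_kind)
    if test == "lrt":
        p = float(chi2.sf(2.0 * (fit.loglik - ll_null), df=1))
    elif test == "wald":
        p = float(fit.p_values[-1])
    else:
        raise ValueError(f"unknown test {test!r}")
    return AssociationResult(
        r2_nagelkerke=r2, p_value=p, threshold=getattr(prs, "threshold", None),
        n_snps=len(getattr(prs, "snp_ids", [])), beta=float(fit.coef[-1]), n=n,
    )
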