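"""Per-SNP association scans with two relatedness corrections.

Two strategies for family-structured cohorts:

* genomic control (GC): run the naive per-SNP OLS scan treating everyone as
  unrelated, then divide the 1-df chi-square statistics by the inflation
  factor lambda = median(chi2) / 0.4549364 (the 1-df chi-square median);
* measured genotype (MG): a mixed model with a polygenic random effect
  whose covariance is proportional to the genomic kinship matrix,
  implemented as the standard two-step approximation — null variance
  components fitted once by maximum likelihood, then per-SNP generalized
  least squares under the fixed covariance.

A conditional scan re-tests region SNPs with the index SNP's dosage as a
covariate, probing allelic heterogeneity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import GenotypeMatrix

log = logging.getLogger(__name__)

CHI2_1DF_MEDIAN = 0.4549364
KINSHIP_RIDGE = 1e-8

ASSOC_COLUMNS = ["snp_id", "chrom", "pos", "counted_allele",
                 "beta", "se", "chi2", "p", "method"]


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix on the 2 x kinship scale."""

    values: np.ndarray
    sample_ids: list[str]
    n_snps_used: int

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t")


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    loglik: float
    degenerate: bool = False

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class GCResult:
    lambda_raw: float  # reported unclamped
    lambda_used: float  # clamped at 1 for correction
    assoc: pd.DataFrame


def _prepare_dosage(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed dosage matrix and a polymorphic-SNP mask."""
    X = genotypes.dosage.copy()
    with np.errstate(invalid="ignore"):
        means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = means[nan_c]
    poly = X.std(axis=0) > 0
    return X, poly


def _finalize(genotypes, mask, beta, se, method) -> pd.DataFrame:
    with np.errstate(divide="ignore"):  # se=0 on a perfect fit -> chi2=inf
        chi2 = (beta / se) ** 2
    p = stats.chi2.sf(chi2, df=1)
    out = genotypes.snps.loc[mask, ["snp_id", "chrom", "pos",
                                    "counted_allele"]].reset_index(drop=True)
    out["beta"] = beta
    out["se"] = se
    out["chi2"] = chi2
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["method"] = method
    return out


def ols_scan(residuals: np.ndarray, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Simple per-SNP OLS of residuals on dosage (with intercept).

    Monomorphic SNPs are skipped with a warning. Returns one row per tested
    SNP: beta, se, Wald chi2 = (beta/se)^2, and the 1-df p-value.
    """
    y = np.asarray(residuals, dtype=float)
    n = y.size
    if n != genotypes.n_samples:
        raise ValueError("residuals and genotypes are not aligned")
    X, poly = _prepare_dosage(genotypes)
    if not poly.all():
        log.warning("ols_scan: skipping %d monomorphic SNPs", (~poly).sum())
    X = X[:, poly]
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    sxy = yc @ Xc
    syy = float(yc @ yc)
    beta = sxy / sxx
    sse = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = sse / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return _finalize(genotypes, poly, beta, se, "ols")


def genomic_kinship(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """Genomic relationship matrix from SNP dosages.

    K_jk = (1/M) sum_m (x_jm - 2 p_m)(x_km - 2 p_m) / (2 p_m (1 - p_m)),
    with p_m the observed counted-allele frequency; missing dosages are
    mean-imputed before centering; fixed SNPs (p in {0, 1}) are excluded.
    """
    if genotypes.n_snps < 100:
        log.warning("genomic_kinship: only %d SNPs; estimates will be noisy",
                    genotypes.n_snps)
    X, _ = _prepare_dosage(genotypes)
    p = X.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    X = X[:, keep]
    p = p[keep]
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    K = (Z @ Z.T) / Z.shape[1]
    return KinshipMatrix((K + K.T) / 2.0, list(genotypes.sample_ids),
                         int(keep.sum()))


def gc_lambda(chi2) -> float:
    """Median-method genomic-control inflation factor for 1-df statistics."""
    arr = np.asarray(chi2, dtype=float)
    if arr.size == 0:
        raise ValueError("empty statistic list")
    if (arr < 0).any():
        raise ValueError("chi-square statistics must be non-negative")
    return float(np.median(arr) / CHI2_1DF_MEDIAN)


def gc_correct(assoc: pd.DataFrame, lam: float) -> GCResult:
    """Divide chi2 by max(lambda, 1) and recompute p-values.

    The correction is a monotone transform, so SNP ranking by p is
    preserved exactly. Lambda below 1 is clamped for correction but
    reported unclamped as the inflation diagnostic.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    used = max(lam, 1.0)
    out = assoc.copy()
    out["chi2"] = assoc["chi2"] / used
    out["p"] = np.clip(stats.chi2.sf(out["chi2"], df=1),
                       np.finfo(float).tiny, 1.0)
    out["se"] = assoc["se"] * np.sqrt(used)
    out["method"] = "gc"
    return GCResult(lambda_raw=float(lam), lambda_used=used, assoc=out)


def fit_null_lmm(residuals: np.ndarray,
                 kinship: KinshipMatrix) -> VarianceComponents:
    """Maximum-likelihood polygenic null model: cov(y) = sg2 K + se2 I.

    One eigendecomposition of K (after a 1e-8 diagonal ridge) followed by a
    bounded 1-D search over the heritability ratio h = sg2 / (sg2 + se2);
    the total variance and a GLS intercept are profiled out analytically.
    When K is indistinguishable from I the components are unidentifiable
    (only their sum is constrained): flagged degenerate with sg2 = 0.
    """
    y = np.asarray(residuals, dtype=float)
    n = y.size
    if n != len(kinship.sample_ids):
        raise ValueError("residuals and kinship are not aligned")
    if n < 50:
        log.warning("fit_null_lmm: n=%d is small; estimates will be unstable", n)
    K = kinship.values + KINSHIP_RIDGE * np.eye(n)
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    ot = U.T @ np.ones(n)

    def profile(h: float) -> tuple[float, float, float]:
        v = h * d + (1.0 - h)
        mu = float(np.sum(ot * yt / v) / np.sum(ot * ot / v))
        r = yt - mu * ot
        s2 = float(np.mean(r * r / v))
        ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2)
                     + np.sum(np.log(v)) + n)
        return ll, s2, mu

    degenerate = float(np.ptp(d)) < 1e-6
    if degenerate:
        _, s2, _ = profile(0.0)
        ll0, _, _ = profile(0.0)
        return VarianceComponents(0.0, s2, ll0, degenerate=True)

    res = optimize.minimize_scalar(lambda h: -profile(h)[0],
                                   bounds=(0.0, 1.0 - 1e-6), method="bounded",
                                   options={"xatol": 1e-8})
    candidates = [0.0, float(res.x)]
    best_h = max(candidates, key=lambda h: profile(h)[0])
    ll, s2, _ = profile(best_h)
    return VarianceComponents(sigma_g2=best_h * s2,
                              sigma_e2=(1.0 - best_h) * s2,
                              loglik=ll)


def lmm_loglik(residuals: np.ndarray, kinship: KinshipMatrix,
               sigma_g2: float, sigma_e2: float) -> float:
    """Gaussian log-likelihood at fixed components (GLS intercept profiled)."""
    y = np.asarray(residuals, dtype=float)
    n = y.size
    K = kinship.values + KINSHIP_RIDGE * np.eye(n)
    d, U = np.linalg.eigh(K)
    v = sigma_g2 * np.maximum(d, 0.0) + sigma_e2
    yt, ot = U.T @ y, U.T @ np.ones(n)
    mu = float(np.sum(ot * yt / v) / np.sum(ot * ot / v))
    r = yt - mu * ot
    return float(-0.5 * (n * np.log(2 * np.pi) + np.sum(np.log(v))
                         + np.sum(r * r / v)))


def mg_scan(residuals: np.ndarray, genotypes: GenotypeMatrix,
            vc: VarianceComponents, kinship: KinshipMatrix) -> pd.DataFrame:
    """Measured-genotype scan: per-SNP GLS under cov = sg2 K + se2 I.

    The covariance shape is fixed from the null fit; the overall residual
    scale is re-estimated per SNP (weighted RSS / (n - 2)), so with
    sg2 = 0 the scan reduces exactly to :func:`ols_scan`.
    """
    y = np.asarray(residuals, dtype=float)
    n = y.size
    K = kinship.values + KINSHIP_RIDGE * np.eye(n)
    d, U = np.linalg.eigh(K)
    v = vc.sigma_g2 * np.maximum(d, 0.0) + vc.sigma_e2
    if np.any(v <= 0):
        raise np.linalg.LinAlgError(
            "singular covariance; increase the kinship ridge above "
            f"{KINSHIP_RIDGE:g}")
    w = 1.0 / v

    X, poly = _prepare_dosage(genotypes)
    if not poly.all():
        log.warning("mg_scan: skipping %d monomorphic SNPs", (~poly).sum())
    Gt = U.T @ X[:, poly]
    yt = U.T @ y
    ot = U.T @ np.ones(n)

    s11 = float(np.sum(w * ot * ot))
    s1y = float(np.sum(w * ot * yt))
    syy = float(np.sum(w * yt * yt))
    s1g = (w * ot) @ Gt
    sgy = (w * yt) @ Gt
    sgg = np.einsum("i,ij,ij->j", w, Gt, Gt)

    det = s11 * sgg - s1g ** 2
    beta = (s11 * sgy - s1g * s1y) / det
    alpha = (sgg * s1y - s1g * sgy) / det
    rss = np.maximum(syy - alpha * s1y - beta * sgy, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 * s11 / det)
    return _finalize(genotypes, poly, beta, se, "mg")


def conditional_scan(residuals: np.ndarray, genotypes: GenotypeMatrix,
                     snp_ids, index_snp_id: str,
                     vc: VarianceComponents | None = None,
                     kinship: KinshipMatrix | None = None) -> pd.DataFrame:
    """Re-test region SNPs with the index SNP's dosage as a covariate.

    OLS by default; pass variance components and kinship for the MG
    (GLS) variant. SNPs perfectly collinear with the index are skipped.
    """
    y = np.asarray(residuals, dtype=float)
    n = y.size
    id_to_col = {s: j for j, s in enumerate(genotypes.snps["snp_id"])}
    if index_snp_id not in id_to_col:
        raise ValueError(f"index SNP {index_snp_id!r} not in genotype matrix")
    X, _ = _prepare_dosage(genotypes)
    x_idx = X[:, id_to_col[index_snp_id]]

    if vc is not None and kinship is not None:
        K = kinship.values + KINSHIP_RIDGE * np.eye(n)
        d, U = np.linalg.eigh(K)
        v = vc.sigma_g2 * np.maximum(d, 0.0) + vc.sigma_e2
        sqrt_w = 1.0 / np.sqrt(v)
        transform = lambda a: sqrt_w * (U.T @ a)
        method = "conditional_mg"
    else:
        transform = lambda a: a
        method = "conditional"

    yt = transform(y)
    it = transform(np.ones(n))
    ct = transform(x_idx)

    rows_mask: list[tuple] = []
    for sid in snp_ids:
        if sid == index_snp_id or sid not in id_to_col:
            continue
        j = id_to_col[sid]
        x = X[:, j]
        if x.std() == 0:
            log.warning("conditional_scan: %s monomorphic, skipped", sid)
            continue
        r = np.corrcoef(x, x_idx)[0, 1]
        if abs(r) > 1 - 1e-10:
            log.warning("conditional_scan: %s collinear with index, skipped", sid)
            continue
        D = np.column_stack([it, transform(x), ct])
        coef, res_ss, rank, _ = np.linalg.lstsq(D, yt, rcond=None)
        rss = float(res_ss[0]) if res_ss.size else float(
            np.sum((yt - D @ coef) ** 2))
        sigma2 = rss / (n - 3)
        cov = sigma2 * np.linalg.inv(D.T @ D)
        rows_mask.append((j, coef[1], np.sqrt(cov[1, 1])))

    rows_mask.sort()  # matrix column order, to match the metadata slice
    mask = np.zeros(genotypes.n_snps, dtype=bool)
    mask[[j for j, *_ in rows_mask]] = True
    betas = np.array([b for _, b, _ in rows_mask])
    ses = np.array([s for *_, s in rows_mask])
    out = _finalize(genotypes, mask, betas, ses, method)
    out["conditioned_on"] = index_snp_id
    return out


def write_assoc_tsv(assoc: pd.DataFrame, path) -> None:
    assoc.to_csv(path, sep="\t", index=False)


def read_assoc_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
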