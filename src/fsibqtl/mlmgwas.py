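"""Mixed-linear-model genome-wide association with kinship and PCA.

The model is y = X b + Z u + e with u ~ N(0, sigma2_g K) and
e ~ N(0, sigma2_e I).  Variance components are estimated once on the null
model by spectral REML (the one-random-effect trick: rotate into the
eigenbasis of the kinship projected off the fixed effects, then optimize a
single variance ratio), and per-marker effects are tested by generalized
least squares with the components held fixed — the standard P3D/EMMAX
approximation.  Structure covariates are principal components of the
centered dosage matrix; kinship is the VanRaden genomic relationship
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assoc import bh_qvalues
from .formats import GenotypeMatrix

__all__ = [
    "vanraden_kinship",
    "genotype_pca",
    "reml_null",
    "mlm_scan",
    "significance_thresholds",
    "qq_data",
    "genomic_inflation",
]


def _imputed_dosage(gmat: GenotypeMatrix) -> np.ndarray:
    """Samples x sites dosage with per-site mean imputation of missing calls."""
    d = gmat.dosage.T.astype(float).copy()
    with np.errstate(invalid="ignore"):
        means = np.nanmean(d, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    nan_r, nan_c = np.where(np.isnan(d))
    d[nan_r, nan_c] = means[nan_c]
    return d


def vanraden_kinship(gmat: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix K = W W' / (2 sum p(1-p)).

    W is the column-centered (2p subtracted) dosage matrix over samples;
    missing dosages are mean-imputed for this computation only.
    """
    d = _imputed_dosage(gmat)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("kinship undefined: every site is monomorphic")
    w = d[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return w @ w.T / denom


def genotype_pca(gmat: GenotypeMatrix, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the centered dosage matrix.

    Returns (scores, variance_fractions): scores is samples x k, and the
    fractions are each component's share of total dosage variance.  Sign
    convention: the entry of largest magnitude in each loading is positive,
    making the rotation deterministic.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k >= gmat.n_samples:
        raise ValueError(f"k={k} must be < n_samples={gmat.n_samples}")
    d = _imputed_dosage(gmat)
    d = d - d.mean(axis=0)
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    for comp in range(min(k, vt.shape[0])):
        j = np.argmax(np.abs(vt[comp]))
        if vt[comp, j] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0
    scores = u[:, :k] * s[:k]
    total = np.sum(s**2)
    fractions = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return scores, fractions


@dataclass
class RemlFit:
    sigma2_g: float
    sigma2_e: float
    delta: float  # sigma2_e / sigma2_g
    loglik: float


_LOG_DELTA_RANGE = (-8.0, 8.0)


def reml_null(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> RemlFit:
    """Spectral REML for the one-random-effect null model.

    Eigendecomposes S K S (S the projection off the column space of X) and
    maximizes the restricted likelihood over delta = sigma2_e / sigma2_g on
    a log grid refined by bounded scalar optimization.  With K = I the
    likelihood is flat in delta and only the total variance is identified.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design X is rank deficient")
    S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    # decompose S (K + I) S: it has exactly p zero eigenvalues (span X), so
    # the top n-p eigenvectors are orthogonal to X even when K is singular
    A = S @ ((K + K.T) / 2.0 + np.eye(n)) @ S
    w, U = np.linalg.eigh(A)
    xi = w[p:] - 1.0  # eigenvalues of the kinship part on the residual space
    if np.min(xi) < -1e-6:
        raise ValueError("kinship matrix is not positive semidefinite")
    xi = np.maximum(xi, 0.0)
    eta = U[:, p:].T @ y
    m = n - p

    def restricted_ll(log_delta: float) -> float:
        delta = 10.0**log_delta
        denom = xi + delta
        ss = np.sum(eta**2 / denom)
        if not np.isfinite(ss) or ss <= 0:
            return -np.inf
        return 0.5 * (m * np.log(m / (2 * np.pi)) - m - m * np.log(ss) - np.sum(np.log(denom)))

    grid = np.linspace(*_LOG_DELTA_RANGE, 81)
    lls = np.array([restricted_ll(g) for g in grid])
    if not np.isfinite(lls).any():
        raise ValueError("restricted likelihood non-finite over the whole delta range")
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -restricted_ll(g), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x)
    delta = 10.0**log_delta
    sigma2_g = float(np.sum(eta**2 / (xi + delta)) / m)
    sigma2_e = float(delta * sigma2_g)
    return RemlFit(sigma2_g=sigma2_g, sigma2_e=sigma2_e, delta=delta,
                   loglik=float(restricted_ll(log_delta)))


def mlm_scan(
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    gmat: GenotypeMatrix,
    maf_floor: float = 0.0,
    fit: RemlFit | None = None,
) -> pd.DataFrame:
    """Per-marker GLS association with variance components fixed at the null.

    The covariance V = sigma2_g K + sigma2_e I is whitened once through the
    eigendecomposition of K; each marker's effect is then an ordinary
    regression in the rotated space, with a two-sided t test (so with K = I
    and no covariates the p-values reduce exactly to the ordinary
    regression F test).  Missing dosages are mean-imputed per site; markers
    below the MAF floor or with zero variance are skipped with a reason.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    ones = np.ones((n, 1))
    X = ones if covariates is None else np.column_stack([ones, covariates])
    if fit is None:
        fit = reml_null(y, X, K)
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    scale = 1.0 / np.sqrt(np.maximum(fit.sigma2_g * w + fit.sigma2_e, 1e-12))
    T = scale[:, None] * U.T  # V^{-1/2}
    yt = T @ y
    Xt = T @ X
    Q, _ = np.linalg.qr(Xt)
    y_res = yt - Q @ (Q.T @ yt)

    d = _imputed_dosage(gmat)
    p_alt = d.mean(axis=0) / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    gt = T @ d
    g_res = gt - Q @ (Q.T @ gt)
    gg = np.sum(g_res**2, axis=0)
    df = n - X.shape[1] - 1

    rows = []
    yy = float(y_res @ y_res)
    for j in range(gmat.n_sites):
        site = gmat.sites.iloc[j]
        base = {"scaffold": site["scaffold"], "pos_bp": int(site["pos_bp"])}
        if maf[j] < maf_floor or gg[j] <= 1e-12:
            rows.append({**base, "beta": np.nan, "se": np.nan, "wald": np.nan,
                         "p_value": np.nan, "skipped": "maf_or_constant"})
            continue
        beta = float(g_res[:, j] @ y_res / gg[j])
        rss = yy - beta**2 * gg[j]
        sigma2 = max(rss, 0.0) / df
        se = float(np.sqrt(sigma2 / gg[j]))
        tstat = beta / se if se > 0 else np.inf
        pval = float(2.0 * stats.t.sf(abs(tstat), df))
        rows.append({**base, "beta": beta, "se": se, "wald": tstat**2,
                     "p_value": pval, "skipped": ""})
    out = pd.DataFrame(rows)
    out.attrs["sigma2_g"] = fit.sigma2_g
    out.attrs["sigma2_e"] = fit.sigma2_e
    out.attrs["delta"] = fit.delta
    return out


def significance_thresholds(
    pvals, m: int | None = None, alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Bonferroni cut (alpha/m) and BH FDR significance flags at ``alpha``."""
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    bonferroni_cut = alpha / m
    q = bh_qvalues(p)
    return float(bonferroni_cut), q <= alpha


def qq_data(pvals) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10(p) pairs for a QQ plot.

    Expected quantiles are -log10((i - 0.5) / m) against the sorted
    observed values, both returned in ascending order.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    observed = -np.log10(np.sort(p)[::-1])
    expected = -np.log10((np.arange(m, 0, -1) - 0.5) / m)
    return expected, observed


def genomic_inflation(pvals) -> float:
    """Genomic-control lambda: median chi-square(1) quantile over its null median."""
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.isf(0.5, df=1))
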