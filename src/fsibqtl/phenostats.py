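"""Phenotype statistics: variance components, heritability, conditional means.

Heading date is modeled with genotype as a random effect and year as a
fixed effect; variance components come from the same spectral REML used by
the GWAS null model, with the kinship replaced by the genotype-incidence
cross-product Z Z'.  Line-mean heritability is
H2 = sigma2_g / (sigma2_g + sigma2_e / n_bar) with n_bar the harmonic mean
of per-genotype record counts.  Conditional means are the fixed-effect-
adjusted BLUPs of genotype effects plus the intercept — shrunken genotype
means — and are the phenotype fed to the marker scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mlmgwas import reml_null

__all__ = [
    "VarianceComponents",
    "variance_components",
    "line_mean_h2",
    "conditional_means",
    "pearson_with_ci",
    "oneway_f_test",
    "regress",
]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    fixed_effects: dict
    n_bar: float  # harmonic-mean records per genotype

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")


def _design(pheno: pd.DataFrame, trait: str):
    df = pheno.dropna(subset=[trait]).reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"no records for trait {trait!r}")
    genotypes = pd.Categorical(df["genotype_id"])
    years = sorted(df["year"].unique())
    X_cols = [np.ones(len(df))]
    names = ["intercept"]
    for yr in years[1:]:
        X_cols.append((df["year"] == yr).to_numpy(dtype=float))
        names.append(f"year_{yr}")
    X = np.column_stack(X_cols)
    Z = pd.get_dummies(genotypes).to_numpy(dtype=float)
    return df, X, names, Z, list(genotypes.categories)


def variance_components(pheno: pd.DataFrame, trait: str = "heading_days") -> VarianceComponents:
    """One-random-effect REML with genotype random and year fixed.

    Raises when every genotype has a single record (sigma2_g is then
    unidentifiable).
    """
    df, X, names, Z, _ = _design(pheno, trait)
    counts = Z.sum(axis=0)
    if counts.max() < 2:
        raise ValueError("all genotypes have a single record; sigma2_g unidentifiable")
    y = df[trait].to_numpy(dtype=float)
    K = Z @ Z.T
    fit = reml_null(y, X, K)
    # GLS fixed effects at the fitted components
    V = fit.sigma2_g * K + fit.sigma2_e * np.eye(len(y))
    Vi_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vi_X, Vi_X.T @ y)
    n_bar = float(len(counts) / np.sum(1.0 / counts))
    return VarianceComponents(
        sigma2_g=fit.sigma2_g,
        sigma2_e=fit.sigma2_e,
        fixed_effects=dict(zip(names, beta.tolist(), strict=True)),
        n_bar=n_bar,
    )


def line_mean_h2(vc: VarianceComponents) -> float:
    """Line-mean heritability H2 = sigma2_g / (sigma2_g + sigma2_e / n_bar)."""
    denom = vc.sigma2_g + vc.sigma2_e / vc.n_bar
    if denom == 0:
        raise ValueError("both variance components are zero; H2 undefined")
    return vc.sigma2_g / denom


def conditional_means(pheno: pd.DataFrame, trait: str = "heading_days") -> pd.Series:
    """Shrunken per-genotype means: intercept + BLUP of the genotype effect.

    u_hat = sigma2_g Z' V^{-1} (y - X beta_hat).  As sigma2_e -> 0 these
    approach the raw genotype means; as sigma2_g -> 0 they collapse to the
    year-adjusted grand mean.
    """
    df, X, names, Z, levels = _design(pheno, trait)
    y = df[trait].to_numpy(dtype=float)
    vc = variance_components(pheno, trait)
    K = Z @ Z.T
    V = vc.sigma2_g * K + vc.sigma2_e * np.eye(len(y))
    Vi_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vi_X, Vi_X.T @ y)
    resid = y - X @ beta
    u = vc.sigma2_g * Z.T @ np.linalg.solve(V, resid)
    return pd.Series(beta[0] + u, index=pd.Index(levels, name="genotype_id"))


def pearson_with_ci(x, y, level: float = 0.95) -> tuple[float, float, float]:
    """Pearson correlation with its Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, have {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.isf((1 - level) / 2)
    return r, float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def oneway_f_test(values, groups) -> tuple[float, int, int, float, float]:
    """One-way ANOVA: returns (F, df1, df2, MSE, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    grand = values.mean()
    ss_between = ss_within = 0.0
    for lab in labels:
        v = values[groups == lab]
        if len(v) == 0:
            raise ValueError(f"group {lab!r} is empty")
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += np.sum((v - v.mean()) ** 2)
    df1 = len(labels) - 1
    df2 = len(values) - len(labels)
    mse = ss_within / df2
    f = (ss_between / df1) / mse if mse > 0 else 0.0
    if ss_between == 0:
        f, p = 0.0, 1.0
    else:
        p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, float(mse), p


def regress(y, x) -> tuple[float, float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, se_slope, p_slope)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for constant x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.stderr), float(res.pvalue)
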