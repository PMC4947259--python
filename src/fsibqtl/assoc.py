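"""Per-family single-marker association scans.

Each pseudo-testcross marker splits a family's offspring into two genotype
classes; a tie-corrected Kruskal-Wallis test on the phenotype against those
classes gives a chi-square-distributed statistic with k-1 degrees of
freedom, and Benjamini-Hochberg q-values control the false discovery rate
within each family x trait scan.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GenotypeMatrix

__all__ = ["kruskal_wallis", "chisq_sf", "bh_qvalues", "run_family_scan", "SkippedTest"]


class SkippedTest(ValueError):
    """A marker test that cannot be run (e.g. one genotype class left)."""


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    H = [12 / (N(N+1))] * sum_j R_j^2 / n_j - 3(N+1), divided by the tie
    correction 1 - sum(t^3 - t) / (N^3 - N) over tie-group sizes t.  Pairs
    with a missing value or group are dropped first.

    Returns (H, df, p) with df = k - 1 and p from the chi-square upper tail.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    if groups.dtype.kind == "f":
        ok &= ~np.isnan(groups)
    values, groups = values[ok], groups[ok]
    labels = np.unique(groups)
    if len(labels) < 2:
        raise SkippedTest(f"only {len(labels)} group(s) after missing-data removal")
    n = len(values)
    ranks = stats.rankdata(values)  # midranks for ties
    h = 0.0
    for lab in labels:
        r = ranks[groups == lab]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0:  # all observations identical
        h = 0.0
    else:
        h /= denom
    h = max(h, 0.0)
    df = len(labels) - 1
    return float(h), int(df), chisq_sf(h, df)


def chisq_sf(x: float, df: int) -> float:
    """Chi-square upper-tail probability (wraps the scipy survival function)."""
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"chi-square statistic must be >= 0, got {x}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.chi2.sf(x, df=df))


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_family_scan(
    family_matrix: GenotypeMatrix,
    phenotype: "pd.Series | dict",
    trait: str = "heading",
    family_id: str | None = None,
) -> pd.DataFrame:
    """Kruskal-Wallis scan of one family's testcross markers against a trait.

    ``phenotype`` maps genotype id -> phenotype value (typically the
    mixed-model conditional mean for heading, or the replicate mean score
    for aftermath heading).  Every sample in the matrix must be present.
    Returns one row per testable marker with columns scaffold, pos_bp, n,
    H, df, p_value, q_value (BH within this scan), plus seg_class when the
    input carries it; markers with a single genotype class are dropped with
    a ``skipped`` count attached via ``DataFrame.attrs``.
    """
    pheno = pd.Series(phenotype)
    ids = family_matrix.samples["sample_id"]
    missing_ids = [s for s in ids if s not in pheno.index]
    if missing_ids:
        raise KeyError(f"phenotype missing for {len(missing_ids)} genotypes: {missing_ids[:5]}")
    y = pheno.loc[ids].to_numpy(dtype=float)
    if family_id is None:
        fam = family_matrix.samples["family_id"].unique()
        family_id = fam[0] if len(fam) == 1 else "mixed"

    rows, skipped = [], 0
    for i in range(family_matrix.n_sites):
        dose = family_matrix.dosage[i]
        try:
            h, df, p = kruskal_wallis(y, dose)
        except SkippedTest:
            skipped += 1
            continue
        site = family_matrix.sites.iloc[i]
        row = {
            "scaffold": site["scaffold"],
            "pos_bp": int(site["pos_bp"]),
            "family_id": family_id,
            "trait": trait,
            "n": int(np.sum(~np.isnan(dose) & ~np.isnan(y))),
            "H": h,
            "df": df,
            "p_value": p,
        }
        if "seg_class" in family_matrix.sites.columns:
            row["seg_class"] = site["seg_class"]
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    else:
        out["q_value"] = pd.Series(dtype=float)
    out.attrs["skipped"] = skipped
    out.attrs["m_tests"] = len(out)
    return out
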