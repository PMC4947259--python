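"""Two-locus linkage disequilibrium from unphased diplotypes.

With unphased genotypes the double heterozygote is ambiguous between the
cis (AB/ab) and trans (Ab/aB) phase, so the haplotype frequency p_AB is
estimated by maximum likelihood — the classical "cubic equation" solution,
here found by EM with multiple starts.  Allele frequencies are fixed at
their sample values, which keeps the optimization one-dimensional; r^2 is
then D^2 / (p_A(1-p_A) p_B(1-p_B)) with D = p_AB - p_A p_B.

Decay curves follow the field convention: estimates sorted by inter-marker
distance (within genomic scaffolds only, never across) and chunked into
fixed-count bins whose mean r^2 and mean distance are plotted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import GenotypeMatrix

__all__ = [
    "MonomorphicError",
    "LDPairEstimate",
    "haplotype_freq_ml",
    "loglik_pab",
    "counts_from_dosage",
    "enumerate_scaffold_pairs",
    "ld_scan",
    "bin_ld_decay",
]

_EPS = 1e-12


class MonomorphicError(ValueError):
    """LD is undefined when either locus is monomorphic in the sample."""


@dataclass
class LDPairEstimate:
    p_a: float
    p_b: float
    p_ab: float
    d: float
    d_prime: float
    r2: float
    loglik: float
    converged: bool
    n: int
    distance_bp: int | None = None


def _known_haplotype_counts(n: np.ndarray) -> tuple[float, float, float, float, float]:
    """Unambiguous haplotype counts from a 3x3 dosage table.

    n[i][j]: count of individuals with i copies of allele A at locus 1 and
    j copies of allele B at locus 2.  Every genotype except the double
    heterozygote resolves into two known haplotypes.
    """
    k_AB = 2 * n[2, 2] + n[2, 1] + n[1, 2]
    k_Ab = 2 * n[2, 0] + n[2, 1] + n[1, 0]
    k_aB = 2 * n[0, 2] + n[0, 1] + n[1, 2]
    k_ab = 2 * n[0, 0] + n[0, 1] + n[1, 0]
    return k_AB, k_Ab, k_aB, k_ab, n[1, 1]


def loglik_pab(p_ab, p_a: float, p_b: float, counts: np.ndarray):
    """Log-likelihood of haplotype frequency p_AB given the genotype table.

    Vectorized over ``p_ab`` (used both by EM convergence checks and by the
    brute-force grid oracle in the test-suite).
    """
    p_ab = np.asarray(p_ab, dtype=float)
    k_AB, k_Ab, k_aB, k_ab, n_dh = _known_haplotype_counts(counts)
    f_AB = p_ab
    f_Ab = p_a - p_ab
    f_aB = p_b - p_ab
    f_ab = 1.0 - p_a - p_b + p_ab
    cis_trans = f_AB * f_ab + f_Ab * f_aB
    terms = (
        k_AB * np.log(np.clip(f_AB, _EPS, None))
        + k_Ab * np.log(np.clip(f_Ab, _EPS, None))
        + k_aB * np.log(np.clip(f_aB, _EPS, None))
        + k_ab * np.log(np.clip(f_ab, _EPS, None))
        + n_dh * np.log(np.clip(cis_trans, _EPS, None))
    )
    return terms


def haplotype_freq_ml(
    counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> LDPairEstimate:
    """Maximum-likelihood haplotype frequency and LD from a 3x3 dosage table.

    Allele frequencies p_A, p_B are fixed at their observed values; the EM
    iteration (E: cis fraction of double heterozygotes; M: reassemble p_AB)
    is run from three starts — just inside each admissible bound and from
    linkage equilibrium — and the best log-likelihood wins.  Ties are
    resolved toward the smaller |D|.
    """
    n = np.asarray(counts, dtype=float)
    if n.shape != (3, 3) or (n < 0).any():
        raise ValueError("counts must be a non-negative 3x3 table")
    total = n.sum()
    if total < 1:
        raise ValueError("need at least one individual")
    dose_a = np.array([0, 1, 2], dtype=float)
    p_a = float((n.sum(axis=1) * dose_a).sum() / (2 * total))
    p_b = float((n.sum(axis=0) * dose_a).sum() / (2 * total))
    if p_a <= 0 or p_a >= 1 or p_b <= 0 or p_b >= 1:
        raise MonomorphicError(f"monomorphic locus: p_A={p_a}, p_B={p_b}")

    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    k_AB, k_Ab, k_aB, k_ab, n_dh = _known_haplotype_counts(n)
    eps = min(1e-6, (hi - lo) / 4) if hi > lo else 0.0
    starts = [lo + eps, p_a * p_b, hi - eps]

    best = None
    for start in starts:
        p_ab = float(np.clip(start, lo, hi))
        converged = False
        for _ in range(max_iter):
            f_AB = p_ab
            f_Ab = p_a - p_ab
            f_aB = p_b - p_ab
            f_ab = 1.0 - p_a - p_b + p_ab
            denom = f_AB * f_ab + f_Ab * f_aB
            f_cis = (f_AB * f_ab / denom) if denom > _EPS else 0.5
            new = (k_AB + f_cis * n_dh) / (2.0 * total)
            new = float(np.clip(new, lo, hi))
            if abs(new - p_ab) < tol:
                p_ab = new
                converged = True
                break
            p_ab = new
        ll = float(loglik_pab(p_ab, p_a, p_b, n))
        d = p_ab - p_a * p_b
        cand = (ll, -abs(d), p_ab, converged)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    ll, _, p_ab, converged = best

    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max <= 0 else d / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDPairEstimate(
        p_a=p_a,
        p_b=p_b,
        p_ab=p_ab,
        d=float(d),
        d_prime=float(d_prime),
        r2=float(min(r2, 1.0)),
        loglik=ll,
        converged=converged,
        n=int(total),
    )


def counts_from_dosage(dose_a: np.ndarray, dose_b: np.ndarray) -> np.ndarray:
    """3x3 genotype table from two dosage vectors (complete pairs only)."""
    ok = ~np.isnan(dose_a) & ~np.isnan(dose_b)
    a = dose_a[ok].astype(int)
    b = dose_b[ok].astype(int)
    table = np.zeros((3, 3), dtype=int)
    np.add.at(table, (a, b), 1)
    return table


def enumerate_scaffold_pairs(gmat: GenotypeMatrix) -> pd.DataFrame:
    """All unordered within-scaffold site pairs with their bp distance.

    LD is computed within genomic scaffolds only — physical distance is not
    defined across scaffolds.  Returns columns i, j (site row indices) and
    distance_bp.
    """
    sites = gmat.sites
    rows = []
    for _, grp in sites.groupby("scaffold", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos_bp"].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                rows.append((idx[a], idx[b], int(abs(pos[b] - pos[a]))))
    return pd.DataFrame(rows, columns=["i", "j", "distance_bp"])


def ld_scan(gmat: GenotypeMatrix, max_pairs: int | None = None) -> pd.DataFrame:
    """ML r^2 for every within-scaffold pair of polymorphic sites.

    Individuals contribute to a pair only when called at both loci.
    Monomorphic or non-converged pairs are excluded (counted in
    ``DataFrame.attrs``).  ``max_pairs`` truncates the enumeration for
    desk-scale runs.
    """
    pairs = enumerate_scaffold_pairs(gmat)
    if max_pairs is not None:
        pairs = pairs.head(max_pairs)
    rows, n_skipped = [], 0
    for i, j, dist in pairs.itertuples(index=False):
        table = counts_from_dosage(gmat.dosage[i], gmat.dosage[j])
        try:
            est = haplotype_freq_ml(table)
        except (MonomorphicError, ValueError):
            n_skipped += 1
            continue
        if not est.converged:
            n_skipped += 1
            continue
        rows.append(
            {
                "i": i,
                "j": j,
                "distance_bp": dist,
                "r2": est.r2,
                "d": est.d,
                "d_prime": est.d_prime,
                "n": est.n,
            }
        )
    out = pd.DataFrame(rows, columns=["i", "j", "distance_bp", "r2", "d", "d_prime", "n"])
    out.attrs["skipped"] = n_skipped
    return out


def bin_ld_decay(pairs: pd.DataFrame, bin_size: int = 1000) -> pd.DataFrame:
    """Fixed-count decay bins: sort by distance, chunk into ``bin_size`` groups.

    Each bin reports mean r^2, mean distance and its pair count; a final
    partial bin is retained and flagged ``partial``.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if len(pairs) == 0:
        return pd.DataFrame(columns=["mean_distance_bp", "mean_r2", "n_pairs", "partial"])
    df = pairs.sort_values("distance_bp", kind="stable").reset_index(drop=True)
    rows = []
    for start in range(0, len(df), bin_size):
        chunk = df.iloc[start : start + bin_size]
        rows.append(
            {
                "mean_distance_bp": float(chunk["distance_bp"].mean()),
                "mean_r2": float(chunk["r2"].mean()),
                "n_pairs": len(chunk),
                "partial": len(chunk) < bin_size,
            }
        )
    return pd.DataFrame(rows)
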