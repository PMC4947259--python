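"""Site filters and pseudo-testcross segregation selection.

The single-marker pipeline works family by family: quality filtering
(GQ >= 30 per call, site mean mapping quality >= 30), presence/minor-allele
frequency filtering (>= 70% present; MAF >= 5% across families or >= 10%
within one), then selection of markers segregating 1:1 — loci homozygous in
one parent and heterozygous in the other, inferred here from offspring
class counts because the parents themselves were never genotyped — and
finally a chi-square test that eliminates markers deviating significantly
from 1:1.  All boundary semantics are inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GenotypeMatrix

logger = logging.getLogger(__name__)

CHI2_CRIT_05 = float(stats.chi2.isf(0.05, df=1))  # 3.8415


class SegregationClass(Enum):
    TESTCROSS_HOMREF_HET = "hom_ref x het"
    TESTCROSS_HOMALT_HET = "hom_alt x het"
    OTHER = "other"


@dataclass(frozen=True)
class SegregationResult:
    seg_class: SegregationClass
    n1: int  # homozygous-class count
    n2: int  # heterozygous-class count
    n_other: int  # residual third-class count
    reason: str = ""


@dataclass
class FilterReport:
    """Marker counts surviving each pipeline stage (non-increasing)."""

    n_input: int = 0
    n_quality: int = 0
    n_presence_maf: int = 0
    n_testcross: int = 0
    n_chi_square: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "input": self.n_input,
                "quality": self.n_quality,
                "presence_maf": self.n_presence_maf,
                "testcross": self.n_testcross,
                "chi_square": self.n_chi_square,
            }
        )


def site_quality_filter(
    gmat: GenotypeMatrix, min_gq: float = 30, min_mq: float = 30
) -> GenotypeMatrix:
    """Mask calls below the GQ floor; drop sites below the MQ floor.

    Values exactly at a floor pass (inclusive).  Sites or calls without a
    quality annotation pass unconditionally.
    """
    out = gmat.copy()
    if out.gq is not None:
        low = out.gq < min_gq  # NaN compares False -> passes
        out.dosage[low] = np.nan
        out.gq[low] = np.nan
    if "mq" in out.sites.columns:
        mq = out.sites["mq"].to_numpy(dtype=float)
        keep = ~(mq < min_mq)  # NaN passes
        out = out.subset_sites(keep)
    return out


def minor_allele_frequencies(gmat: GenotypeMatrix) -> np.ndarray:
    """Per-site MAF from non-missing allele counts (NaN for empty sites)."""
    n_called = np.sum(~np.isnan(gmat.dosage), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.nansum(gmat.dosage, axis=1) / (2.0 * n_called)
    p_alt[n_called == 0] = np.nan
    return np.minimum(p_alt, 1.0 - p_alt)


def presence_maf_filter(
    gmat: GenotypeMatrix, min_presence: float = 0.70, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Keep sites present in >= min_presence of samples with MAF >= min_maf.

    MAF is computed from non-missing allele counts; sites with zero
    non-missing calls are dropped and counted in the log.
    """
    for name, v in (("min_presence", min_presence), ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    present = np.mean(~np.isnan(gmat.dosage), axis=1)
    maf = minor_allele_frequencies(gmat)
    empty = np.isnan(maf)
    if empty.any():
        logger.info("presence_maf_filter: dropped %d all-missing sites", int(empty.sum()))
    keep = (present >= min_presence) & ~empty & (maf >= min_maf)
    return gmat.subset_sites(keep)


def classify_segregation(
    site_calls: np.ndarray, third_class_tolerance: float = 0.05, min_calls: int = 20
) -> SegregationResult:
    """Classify one site's offspring dosages into a pseudo-testcross class.

    A site is TESTCROSS_* when one homozygous class plus the heterozygous
    class account for at least (1 - tolerance) of the non-missing calls and
    the residual third class is at most tolerance (a genotyping-error
    allowance — a strict two-class rule would discard nearly everything at
    realistic GBS error rates).  Below ``min_calls`` non-missing calls the
    site is OTHER.
    """
    calls = np.asarray(site_calls, dtype=float)
    calls = calls[~np.isnan(calls)]
    n = len(calls)
    n_homref = int(np.sum(calls == 0))
    n_het = int(np.sum(calls == 1))
    n_homalt = int(np.sum(calls == 2))
    if n < min_calls:
        return SegregationResult(SegregationClass.OTHER, 0, 0, n, reason=f"only {n} calls")
    if n_homref >= n_homalt:
        hom, third, cls = n_homref, n_homalt, SegregationClass.TESTCROSS_HOMREF_HET
    else:
        hom, third, cls = n_homalt, n_homref, SegregationClass.TESTCROSS_HOMALT_HET
    if third <= third_class_tolerance * n and hom > 0 and n_het > 0:
        return SegregationResult(cls, n1=hom, n2=n_het, n_other=third)
    return SegregationResult(
        SegregationClass.OTHER, n1=hom, n2=n_het, n_other=third, reason="three genotype classes"
    )


def chi_square_1to1(n1: int, n2: int) -> tuple[float, float]:
    """Pearson chi-square for a 1:1 segregation, df=1, no continuity correction.

    statistic = (n1 - n2)^2 / (n1 + n2).
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    total = n1 + n2
    if total == 0:
        raise ValueError("need at least one call")
    statistic = (n1 - n2) ** 2 / total
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def select_testcross_markers(
    family_matrix: GenotypeMatrix,
    min_presence: float = 0.70,
    min_maf: float = 0.10,
    alpha: float = 0.05,
    third_class_tolerance: float = 0.05,
    min_calls: int = 20,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Full per-family marker selection: presence/MAF -> 1:1 class -> chi-square.

    The returned matrix contains the surviving markers with residual
    third-class calls set missing and per-site columns seg_class, n1, n2,
    chi2, chi2_p appended to ``sites``.  The report carries the stage
    counts (the per-family analogue of a pipeline marker-count table).
    """
    report = FilterReport(n_input=family_matrix.n_sites)
    m = site_quality_filter(family_matrix)
    report.n_quality = m.n_sites
    m = presence_maf_filter(m, min_presence=min_presence, min_maf=min_maf)
    report.n_presence_maf = m.n_sites

    seg_results = [
        classify_segregation(m.dosage[i], third_class_tolerance, min_calls)
        for i in range(m.n_sites)
    ]
    is_tc = np.array([r.seg_class is not SegregationClass.OTHER for r in seg_results])
    m = m.subset_sites(is_tc)
    seg_results = [r for r, ok in zip(seg_results, is_tc, strict=True) if ok]
    report.n_testcross = m.n_sites

    # residual third-class calls become missing for downstream tests
    for i, r in enumerate(seg_results):
        if r.n_other:
            third_dose = 2.0 if r.seg_class is SegregationClass.TESTCROSS_HOMREF_HET else 0.0
            m.dosage[i, m.dosage[i] == third_dose] = np.nan

    stats_p = [chi_square_1to1(r.n1, r.n2) for r in seg_results]
    keep = np.array([p >= alpha for _, p in stats_p], dtype=bool)
    sites = m.sites.copy()
    sites["seg_class"] = [r.seg_class.value for r in seg_results]
    sites["n1"] = [r.n1 for r in seg_results]
    sites["n2"] = [r.n2 for r in seg_results]
    sites["chi2"] = [s for s, _ in stats_p]
    sites["chi2_p"] = [p for _, p in stats_p]
    m = GenotypeMatrix(sites=sites, samples=m.samples, dosage=m.dosage, gq=m.gq)
    m = m.subset_sites(keep)
    report.n_chi_square = m.n_sites
    return m, report
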