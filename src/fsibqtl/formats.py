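"""Containers and readers/writers for the pipeline's on-disk artifacts.

The genotype interchange format is plain VCF v4.2 (GT and GQ per call,
INFO/MQ per site).  Phenotypes travel as CSV, the genome-zipper anchoring
table and the genetic linkage map as tab-separated text with header rows.
Missing dosage is encoded as NaN and is always distinct from dosage 0;
nothing is zero-imputed on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

SITE_COLUMNS = ["scaffold", "pos_bp", "ref", "alt", "mq"]


class VcfParseError(ValueError):
    """Raised when a VCF header or record cannot be interpreted."""


class SchemaError(ValueError):
    """Raised when a delimited input lacks a mandatory column."""


@dataclass
class GenotypeMatrix:
    """Markers x individuals diploid dosage calls plus per-site metadata.

    dosage[i, j] is the alternate-allele count (0/1/2) of sample j at site i,
    NaN when the call is missing.  ``gq`` mirrors the shape of ``dosage``
    (NaN where no genotype quality was emitted).  ``sites`` may carry extra
    columns (e.g. simulated lg / pos_cm truth metadata); the canonical ones
    are scaffold, pos_bp (1-based), ref, alt, mq.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    dosage: np.ndarray
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        n_sites, n_samples = self.dosage.shape
        if len(self.sites) != n_sites or len(self.samples) != n_samples:
            raise ValueError(
                f"dimension mismatch: {len(self.sites)} sites x "
                f"{len(self.samples)} samples vs dosage {self.dosage.shape}"
            )
        if self.gq is not None and self.gq.shape != self.dosage.shape:
            raise ValueError("gq shape differs from dosage shape")
        for col in ("scaffold", "pos_bp"):
            if col not in self.sites.columns:
                raise ValueError(f"sites table lacks column {col!r}")

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            sites=self.sites.iloc[idx],
            samples=self.samples,
            dosage=self.dosage[idx],
            gq=None if self.gq is None else self.gq[idx],
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            sites=self.sites,
            samples=self.samples.iloc[idx],
            dosage=self.dosage[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
        )

    def family(self, family_id: str) -> "GenotypeMatrix":
        """Restrict to the samples of one full-sib family."""
        mask = (self.samples["family_id"] == family_id).to_numpy()
        if not mask.any():
            raise KeyError(f"no samples with family_id {family_id!r}")
        return self.subset_samples(mask)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=self.sites.copy(),
            samples=self.samples.copy(),
            dosage=self.dosage.copy(),
            gq=None if self.gq is None else self.gq.copy(),
        )


@dataclass
class ReadReport:
    """Counters for records a reader rejected or skipped (never silent)."""

    n_read: int = 0
    n_kept: int = 0
    n_multiallelic: int = 0
    n_rejected: int = 0
    reasons: dict = field(default_factory=dict)

    def reject(self, reason: str, n: int = 1) -> None:
        self.n_rejected += n
        self.reasons[reason] = self.reasons.get(reason, 0) + n


def read_vcf(path, family_map: dict | None = None) -> tuple[GenotypeMatrix, ReadReport]:
    """Read a VCF v4.2 into a :class:`GenotypeMatrix`.

    Dosage is the alternate-allele count from GT; ``./.`` is missing.
    Absent GQ or INFO/MQ is treated as passing (NaN).  Multiallelic sites
    are skipped and counted in the returned :class:`ReadReport`.

    ``family_map`` maps sample id -> family id; unmapped samples get the
    prefix of the id before the first ``_`` as their family.
    """
    from cyvcf2 import VCF

    report = ReadReport()
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib reports its own line context
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    rows = []
    dosages = []
    gqs = []
    any_gq = False
    for rec_no, var in enumerate(vcf, start=1):
        report.n_read += 1
        if len(var.ALT) != 1:
            report.n_multiallelic += 1
            report.reject("multiallelic")
            continue
        gts = np.array(var.genotypes, dtype=object)
        dose = np.empty(len(sample_ids))
        for j, g in enumerate(gts):
            a, b = g[0], g[1]
            dose[j] = MISSING if (a < 0 or b < 0) else float(a + b)
        gq_arr = np.full(len(sample_ids), np.nan)
        try:
            raw_gq = var.format("GQ")
        except KeyError:  # GQ absent from the header entirely
            raw_gq = None
        if raw_gq is not None:
            any_gq = True
            vals = np.asarray(raw_gq, dtype=float).reshape(len(sample_ids), -1)[:, 0]
            vals[vals < 0] = np.nan  # htslib sentinel for missing
            gq_arr = vals
        mq = var.INFO.get("MQ")
        rows.append(
            {
                "scaffold": var.CHROM,
                "pos_bp": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "mq": np.nan if mq is None else float(mq),
            }
        )
        dosages.append(dose)
        gqs.append(gq_arr)
    report.n_kept = len(rows)
    if report.n_multiallelic:
        logger.info("read_vcf: skipped %d multiallelic sites", report.n_multiallelic)

    families = []
    for s in sample_ids:
        if family_map and s in family_map:
            families.append(family_map[s])
        else:
            families.append(s.split("_")[0])
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    matrix = GenotypeMatrix(
        sites=sites,
        samples=pd.DataFrame({"sample_id": sample_ids, "family_id": families}),
        dosage=np.array(dosages).reshape(len(rows), len(sample_ids)),
        gq=np.array(gqs).reshape(len(rows), len(sample_ids)) if any_gq else None,
    )
    return matrix, report


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as VCF v4.2 (round-trips with read_vcf)."""
    sites = matrix.sites
    order = np.lexsort((sites["pos_bp"].to_numpy(), sites["scaffold"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=fsibqtl\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for scaf in pd.unique(sites["scaffold"].to_numpy()[order]):
            fh.write(f"##contig=<ID={scaf}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += list(matrix.samples["sample_id"])
        fh.write("\t".join(header) + "\n")
        has_gq = matrix.gq is not None
        fmt = "GT:GQ" if has_gq else "GT"
        for i in order:
            row = sites.iloc[i]
            mq = row.get("mq", np.nan)
            info = "." if pd.isna(mq) else f"MQ={float(mq):g}"
            fields = [
                str(row["scaffold"]),
                str(int(row["pos_bp"])),
                ".",
                str(row.get("ref", "A")),
                str(row.get("alt", "T")),
                ".",
                ".",
                info,
                fmt,
            ]
            for j in range(matrix.n_samples):
                d = matrix.dosage[i, j]
                gt = "./." if np.isnan(d) else _GT_CODE[float(d)]
                if has_gq:
                    q = matrix.gq[i, j]
                    gt += ":." if np.isnan(q) else f":{int(q)}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Delimited tables


def _require_columns(df: pd.DataFrame, cols, what: str, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file {path} lacks mandatory column(s): {missing}")


def read_phenotypes(path) -> tuple[pd.DataFrame, ReadReport]:
    """Read the long-format phenotype CSV.

    Columns: genotype_id, family_id, replicate, year, then one or both of
    heading_days (non-negative real) and aftermath_score (integer 1..9).
    Rows with an out-of-range aftermath score or negative heading are
    rejected with a warning and counted.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["genotype_id", "family_id", "replicate", "year"], "phenotype", path)
    if "heading_days" not in df.columns and "aftermath_score" not in df.columns:
        raise SchemaError(f"phenotype file {path} has no trait column")
    report = ReadReport(n_read=len(df))
    keep = np.ones(len(df), dtype=bool)
    if "aftermath_score" in df.columns:
        score = df["aftermath_score"]
        bad = score.notna() & ~score.isin(range(1, 10))
        if bad.any():
            warnings.warn(f"rejected {int(bad.sum())} rows with aftermath_score outside 1..9")
            report.reject("aftermath_score_out_of_range", int(bad.sum()))
            keep &= ~bad.to_numpy()
    if "heading_days" in df.columns:
        bad = df["heading_days"].notna() & (df["heading_days"] < 0)
        if bad.any():
            warnings.warn(f"rejected {int(bad.sum())} rows with negative heading_days")
            report.reject("negative_heading_days", int(bad.sum()))
            keep &= ~bad.to_numpy()
    out = df[keep].reset_index(drop=True)
    report.n_kept = len(out)
    return out, report


def read_zipper(path) -> pd.DataFrame:
    """Read the scaffold -> (linkage group, cM) anchoring table (TSV).

    One anchor per scaffold; on duplicates the first row wins and a warning
    is logged.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["scaffold", "lg", "pos_cm"], "zipper", path)
    dup = df.duplicated(subset="scaffold")
    if dup.any():
        warnings.warn(f"zipper table: {int(dup.sum())} duplicate scaffold anchors; first kept")
        df = df[~dup]
    df = df.reset_index(drop=True)
    df["lg"] = df["lg"].astype(int)
    df["pos_cm"] = df["pos_cm"].astype(float)
    return df


def read_map(path) -> pd.DataFrame:
    """Read the genetic linkage map (TSV: marker_id, lg, pos_cm)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["marker_id", "lg", "pos_cm"], "genetic map", path)
    if df["marker_id"].duplicated().any():
        raise SchemaError(f"genetic map {path} has duplicate marker ids")
    df = df.sort_values(["lg", "pos_cm"], kind="stable").reset_index(drop=True)
    df["lg"] = df["lg"].astype(int)
    df["pos_cm"] = df["pos_cm"].astype(float)
    return df


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)
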