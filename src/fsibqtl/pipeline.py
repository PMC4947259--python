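"""End-to-end pipeline: simulate -> filter -> pheno-stats -> scan -> anchor -> ld -> gwas.

One global seed is fanned out to per-stage sub-seeds by a fixed derivation
(SeedSequence spawn keys), so any stage can be rerun independently and a
rerun with the same config is bit-identical for deterministic stages.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anchor import anchor_markers, bin_by_map_intervals, heatmap_matrix
from .assoc import run_family_scan
from .filtering import presence_maf_filter, select_testcross_markers, site_quality_filter
from .formats import GenotypeMatrix, write_table, write_vcf
from .ldtools import bin_ld_decay, ld_scan
from .mlmgwas import genomic_inflation, genotype_pca, mlm_scan, significance_thresholds, vanraden_kinship
from .phenostats import conditional_means, line_mean_h2, pearson_with_ci, variance_components
from .simdata import SimConfig, simulate_study

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "min_gq": 30,
    "min_mq": 30,
    "min_presence": 0.70,
    "min_maf_global": 0.05,
    "min_maf_family": 0.10,
    "chi2_alpha": 0.05,
    "fdr_alpha": 0.05,
    "ld_bin_size": 1000,
    "n_pcs": 3,
    "ld_max_pairs": 50000,
}


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the global seed."""
    ss = np.random.SeedSequence([seed, int.from_bytes(stage.encode(), "little") % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run every stage on a simulated study and write a manifest.

    ``config`` keys: any :class:`SimConfig` field plus entries of
    DEFAULT_PARAMS and ``seed``.  Returns a summary dict (also written to
    ``summary.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **{k: v for k, v in config.items() if k in DEFAULT_PARAMS}}
    sim_fields = set(SimConfig.__dataclass_fields__)
    sim_kwargs = {k: v for k, v in config.items() if k in sim_fields}
    unknown = set(config) - sim_fields - set(DEFAULT_PARAMS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    sim_kwargs["seed"] = _stage_seed(seed, "simulate")
    sim = SimConfig(**sim_kwargs)

    # -- simulate -----------------------------------------------------------
    study = simulate_study(sim)
    gmat: GenotypeMatrix = study["genotypes"]
    pheno: pd.DataFrame = study["phenotypes"]
    write_vcf(gmat, out / "genotypes.vcf")
    pheno.to_csv(out / "phenotypes.csv", index=False)
    write_table(study["gmap"], out / "genetic_map.tsv")
    write_table(study["zipper"], out / "zipper.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(study["truth"], fh, indent=1)

    # -- phenotype statistics ----------------------------------------------
    vc = variance_components(pheno, "heading_days")
    h2 = line_mean_h2(vc)
    cmeans = conditional_means(pheno, "heading_days")
    cmeans.rename("conditional_mean").to_csv(out / "conditional_means.csv")
    ymeans = (
        pheno.dropna(subset=["heading_days"])
        .groupby(["genotype_id", "year"])["heading_days"]
        .mean()
        .unstack()
    )
    years = list(ymeans.columns)
    r_year, ci_lo, ci_hi = pearson_with_ci(ymeans[years[0]], ymeans[years[1]])
    aftermath = (
        pheno.dropna(subset=["aftermath_score"]).groupby("genotype_id")["aftermath_score"].mean()
    )

    # -- global filter + GWAS ----------------------------------------------
    filt = site_quality_filter(gmat, params["min_gq"], params["min_mq"])
    filt = presence_maf_filter(filt, params["min_presence"], params["min_maf_global"])
    y = cmeans.loc[filt.samples["sample_id"]].to_numpy()
    K = vanraden_kinship(filt)
    pcs, pc_var = genotype_pca(filt, k=params["n_pcs"])
    gwas = mlm_scan(y, pcs, K, filt, maf_floor=params["min_maf_global"])
    pvals = gwas["p_value"].dropna().to_numpy()
    bonf, fdr_flags = significance_thresholds(pvals, alpha=params["fdr_alpha"])
    gwas.to_csv(out / "gwas.tsv", sep="\t", index=False)

    # -- LD decay -----------------------------------------------------------
    ld_pairs = ld_scan(filt, max_pairs=params["ld_max_pairs"])
    ld_bins = bin_ld_decay(ld_pairs, bin_size=params["ld_bin_size"])
    ld_pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
    ld_bins.to_csv(out / "ld_bins.tsv", sep="\t", index=False)

    # -- per-family selection + scans + anchoring ---------------------------
    families = list(gmat.samples["family_id"].unique())
    reports = {}
    scans = []
    for fam in families:
        fam_mat = gmat.family(fam)
        sel, report = select_testcross_markers(
            fam_mat,
            min_presence=params["min_presence"],
            min_maf=params["min_maf_family"],
            alpha=params["chi2_alpha"],
        )
        reports[fam] = report.as_series()
        scan = run_family_scan(sel, cmeans, trait="heading", family_id=fam)
        anchored = anchor_markers(scan, study["zipper"])
        scans.append(anchored)
        if fam == families[-1]:
            am_scan = run_family_scan(sel, aftermath, trait="aftermath", family_id=fam)
            anchor_markers(am_scan, study["zipper"]).to_csv(
                out / f"scan_aftermath_{fam}.tsv", sep="\t", index=False
            )
    all_scans = pd.concat(scans, ignore_index=True)
    all_scans.to_csv(out / "scan_heading.tsv", sep="\t", index=False)
    pd.DataFrame(reports).to_csv(out / "filter_report.tsv", sep="\t")

    # heatmap for the LG carrying the largest heading QTL
    lg_counts = all_scans.loc[all_scans["lg"] != "--", "lg"]
    heat_bounds = (0.0, 0.0)
    if len(lg_counts):
        lg = int(lg_counts.mode().iloc[0])
        cells = pd.concat(
            [
                bin_by_map_intervals(s[s["lg"] != "--"], study["gmap"], fam, lg)
                for fam, s in zip(families, scans, strict=True)
                if (s["lg"] == lg).any()
            ],
            ignore_index=True,
        )
        matrix, heat_bounds = heatmap_matrix(cells, families)
        matrix.to_csv(out / f"heatmap_lg{lg}.tsv", sep="\t")

    summary = {
        "n_samples": gmat.n_samples,
        "n_markers_simulated": gmat.n_sites,
        "n_markers_global_filter": filt.n_sites,
        "sigma2_g": vc.sigma2_g,
        "sigma2_e": vc.sigma2_e,
        "h2_line_mean": h2,
        "r_between_years": r_year,
        "r_between_years_ci": [ci_lo, ci_hi],
        "gwas_lambda": genomic_inflation(pvals),
        "gwas_bonferroni_cut": bonf,
        "gwas_n_fdr_significant": int(fdr_flags.sum()),
        "ld_n_pairs": len(ld_pairs),
        "ld_first_bin_mean_r2": float(ld_bins["mean_r2"].iloc[0]) if len(ld_bins) else None,
        "ld_last_bin_mean_r2": float(ld_bins["mean_r2"].iloc[-1]) if len(ld_bins) else None,
        "family_testcross_survivors": {f: int(r["chi_square"]) for f, r in reports.items()},
        "min_q_heading": float(all_scans["q_value"].min()) if len(all_scans) else None,
        "heatmap_scale": list(heat_bounds),
    }
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {**sim_kwargs, **params},
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return summary
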