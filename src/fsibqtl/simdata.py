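"""Synthetic full-sib families, linkage maps, zipper tables and phenotypes.

The generator emulates the study design the pipeline is built for: six
pair-cross full-sib families of 60 offspring each, genotyped at GBS-like
biallelic SNPs with heavy missingness, scored for days-to-heading over two
years x two field replicates and for an ordinal 1-9 aftermath-heading score.

Meiosis uses the Haldane (no crossover interference) model: crossovers are
a Poisson process on the cM scale, so the recombination fraction across a
gap of d cM is r = (1 - exp(-2d/100)) / 2.  Physical coordinates are
assigned by cutting each linkage group into scaffolds and scaling cM to bp
with a fixed constant (default 1 Mb/cM), which gives the LD-decay machinery
realistic within-scaffold distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import GenotypeMatrix

__all__ = [
    "QTL",
    "QTLSpec",
    "ParentPair",
    "SimConfig",
    "make_genetic_map",
    "make_loci",
    "make_parent_pair",
    "simulate_family",
    "simulate_phenotypes",
    "apply_gbs_noise",
    "make_zipper",
    "simulate_study",
    "haldane_r",
]


def haldane_r(d_cm: float) -> float:
    """Recombination fraction for a map distance of ``d_cm`` centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm) / 100.0))


@dataclass(frozen=True)
class QTL:
    lg: int
    pos_cm: float
    additive_effect: float  # days (heading) or latent units (aftermath)
    trait: str = "heading"  # "heading" | "aftermath_latent"


@dataclass
class QTLSpec:
    """Truth model for the phenotype generator."""

    qtls: list[QTL] = field(default_factory=list)
    family_mean: float = 50.0  # days to heading from April 1st
    year_effects: dict = field(default_factory=lambda: {2014: 0.0, 2015: 3.0})
    residual_sd: float = 3.6
    aftermath_coupling: float = -0.4  # latent units per day of heading genetic value
    aftermath_sd: float = 1.0
    aftermath_center: float = 3.0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")


@dataclass
class ParentPair:
    """Two phased parents of one full-sib family.

    ``hap1`` / ``hap2`` are (2, n_loci) arrays of alleles in {0, 1}, one row
    per homologous chromosome.
    """

    hap1: np.ndarray
    hap2: np.ndarray
    family_id: str = "F1"
    cross_mode: str = "F2_sibmated"  # or "F1_fullsib"

    def __post_init__(self) -> None:
        if self.hap1.shape != self.hap2.shape or self.hap1.shape[0] != 2:
            raise ValueError("parent haplotypes must both be (2, n_loci)")
        if self.cross_mode not in ("F2_sibmated", "F1_fullsib"):
            raise ValueError(f"unknown cross_mode {self.cross_mode!r}")

    @property
    def n_loci(self) -> int:
        return self.hap1.shape[1]


@dataclass
class SimConfig:
    """End-to-end study configuration.  Defaults mirror the study design."""

    n_families: int = 6
    n_offspring_per_family: int = 60
    n_lgs: int = 7
    lg_length_cm: float = 100.0
    n_markers: int = 5000
    missing_rate: float = 0.20
    genotype_error_rate: float = 0.01
    unanchored_scaffold_fraction: float = 0.70
    scaffolds_per_lg: int = 40
    bp_per_cm: float = 1_000_000.0
    cross_mode: str = "F2_sibmated"
    n_f1: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "genotype_error_rate", "unanchored_scaffold_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# Map and physical coordinates


def make_genetic_map(n_lgs: int, lg_length_cm: float, n_markers: int, seed: int) -> pd.DataFrame:
    """Markers uniformly spread over ``n_lgs`` linkage groups, with jitter.

    Returns the map as a DataFrame (marker_id, lg, pos_cm), sorted by
    (lg, pos_cm); deterministic for a fixed seed.
    """
    if n_lgs < 1 or lg_length_cm <= 0 or n_markers < 2 * n_lgs:
        raise ValueError(
            f"need n_lgs >= 1, lg_length_cm > 0 and n_markers >= 2*n_lgs "
            f"(got {n_lgs}, {lg_length_cm}, {n_markers})"
        )
    rng = np.random.default_rng(seed)
    per_lg = np.full(n_lgs, n_markers // n_lgs)
    per_lg[: n_markers % n_lgs] += 1
    rows = []
    for lg in range(1, n_lgs + 1):
        m = per_lg[lg - 1]
        grid = (np.arange(m) + 0.5) / m * lg_length_cm
        jitter = rng.uniform(-0.4, 0.4, size=m) * lg_length_cm / m
        pos = np.sort(np.clip(grid + jitter, 0.0, lg_length_cm))
        for k, p in enumerate(pos):
            rows.append({"marker_id": f"M{lg}_{k:05d}", "lg": lg, "pos_cm": float(p)})
    return pd.DataFrame(rows)


def make_loci(
    gmap: pd.DataFrame, scaffolds_per_lg: int = 40, bp_per_cm: float = 1_000_000.0
) -> pd.DataFrame:
    """Assign each map marker a scaffold and a 1-based bp position.

    Each linkage group is cut into ``scaffolds_per_lg`` equal cM chunks; a
    chunk is one scaffold, and bp within a scaffold scales linearly from the
    chunk's cM offset.  Deterministic (no randomness).
    """
    loci = gmap.copy()
    lg_len = loci.groupby("lg")["pos_cm"].transform("max").to_numpy()
    span = np.maximum(lg_len, 1e-9) / scaffolds_per_lg
    chunk = np.minimum((loci["pos_cm"].to_numpy() / span).astype(int), scaffolds_per_lg - 1)
    loci["scaffold"] = [
        f"scaffold_{lg}_{c:03d}" for lg, c in zip(loci["lg"], chunk, strict=True)
    ]
    offset_cm = loci["pos_cm"].to_numpy() - chunk * span
    loci["pos_bp"] = np.round(offset_cm * bp_per_cm).astype(np.int64) + 1
    # enforce strictly increasing bp within a scaffold (cM ties would collide)
    for _, idx in loci.groupby("scaffold").groups.items():
        vals = loci.loc[idx, "pos_bp"].to_numpy()
        for i in range(1, len(vals)):
            if vals[i] <= vals[i - 1]:
                vals[i] = vals[i - 1] + 1
        loci.loc[idx, "pos_bp"] = vals
    loci["ref"] = "A"
    loci["alt"] = "T"
    loci["mq"] = 60.0
    return loci


# ---------------------------------------------------------------------------
# Parents and meiosis


def make_parent_pair(
    loci: pd.DataFrame,
    family_id: str,
    seed: int,
    p_testcross: float = 0.5,
    p_hethet: float = 0.3,
    cross_mode: str = "F2_sibmated",
) -> ParentPair:
    """Draw phased parental diplotypes for one pair cross.

    Per locus: with probability ``p_testcross`` one parent is homozygous and
    the other heterozygous (the pseudo-testcross configuration, split evenly
    between hom-ref x het and hom-alt x het); with probability ``p_hethet``
    both are heterozygous; otherwise both homozygous (monomorphic within the
    family).  The real parents were never genotyped, so parental truth
    exists only in simulation.
    """
    rng = np.random.default_rng(seed)
    n = len(loci)
    u = rng.random(n)
    h1 = np.zeros((2, n), dtype=np.int8)
    h2 = np.zeros((2, n), dtype=np.int8)
    het = np.array([0, 1], dtype=np.int8)
    for i in range(n):
        if u[i] < p_testcross:
            hom_allele = np.int8(rng.random() < 0.5)
            hom = np.array([hom_allele, hom_allele])
            if rng.random() < 0.5:
                h1[:, i], h2[:, i] = hom, rng.permutation(het)
            else:
                h1[:, i], h2[:, i] = rng.permutation(het), hom
        elif u[i] < p_testcross + p_hethet:
            h1[:, i] = rng.permutation(het)
            h2[:, i] = rng.permutation(het)
        else:
            a = np.int8(rng.random() < 0.5)
            b = np.int8(rng.random() < 0.5)
            h1[:, i] = a
            h2[:, i] = b
    return ParentPair(hap1=h1, hap2=h2, family_id=family_id, cross_mode=cross_mode)


def _gametes(haps: np.ndarray, lg: np.ndarray, pos_cm: np.ndarray,
             n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` gametes from one phased parent under the Haldane model.

    Crossover count on each linkage group is Poisson(L/100); crossover
    positions are uniform on [0, L]; the starting homolog is fair-coin.
    Returns an (n, n_loci) allele array.
    """
    n_loci = haps.shape[1]
    out = np.empty((n, n_loci), dtype=np.int8)
    for g in np.unique(lg):
        idx = np.flatnonzero(lg == g)
        p = pos_cm[idx]
        L = p.max() if len(p) else 0.0
        n_x = rng.poisson(L / 100.0, size=n)
        for k in range(n):
            if n_x[k]:
                xpos = np.sort(rng.uniform(0.0, L, size=n_x[k]))
                n_below = np.searchsorted(xpos, p, side="right")
            else:
                n_below = np.zeros(len(idx), dtype=int)
            start = rng.integers(0, 2)
            phase = (start + n_below) % 2
            out[k, idx] = haps[phase, idx]
    return out


def simulate_family(
    parents: ParentPair, loci: pd.DataFrame, n_offspring: int, seed: int, n_f1: int = 30
) -> GenotypeMatrix:
    """Simulate one full-sib family from a phased parent pair.

    In ``F1_fullsib`` mode each offspring takes one gamete per parent.  In
    ``F2_sibmated`` mode (the default cross), an F1 cohort of ``n_f1``
    plants is produced first and offspring are random matings of two
    distinct F1 individuals — a single pair cross followed by seed
    multiplication.
    """
    if parents.n_loci != len(loci):
        raise ValueError(
            f"parents are phased over {parents.n_loci} loci but the map has {len(loci)}"
        )
    rng = np.random.default_rng(seed)
    lg = loci["lg"].to_numpy()
    pos = loci["pos_cm"].to_numpy()
    if parents.cross_mode == "F1_fullsib":
        ga = _gametes(parents.hap1, lg, pos, n_offspring, rng)
        gb = _gametes(parents.hap2, lg, pos, n_offspring, rng)
        dosage = (ga + gb).astype(float)
    else:
        f1a = _gametes(parents.hap1, lg, pos, n_f1, rng)
        f1b = _gametes(parents.hap2, lg, pos, n_f1, rng)
        dams = rng.integers(0, n_f1, size=n_offspring)
        sires = (dams + 1 + rng.integers(0, n_f1 - 1, size=n_offspring)) % n_f1
        dosage = np.empty((n_offspring, parents.n_loci))
        for k in range(n_offspring):
            f1_hap_d = np.stack([f1a[dams[k]], f1b[dams[k]]])
            f1_hap_s = np.stack([f1a[sires[k]], f1b[sires[k]]])
            gd = _gametes(f1_hap_d, lg, pos, 1, rng)[0]
            gs = _gametes(f1_hap_s, lg, pos, 1, rng)[0]
            dosage[k] = gd + gs
    samples = pd.DataFrame(
        {
            "sample_id": [f"{parents.family_id}_{k:03d}" for k in range(n_offspring)],
            "family_id": parents.family_id,
        }
    )
    site_cols = ["scaffold", "pos_bp", "ref", "alt", "mq", "lg", "pos_cm", "marker_id"]
    sites = loci[[c for c in site_cols if c in loci.columns]].copy()
    return GenotypeMatrix(sites=sites, samples=samples, dosage=dosage.T)


# ---------------------------------------------------------------------------
# Phenotypes


def _qtl_dosage(gmat: GenotypeMatrix, qtl: QTL) -> np.ndarray:
    """Dosage vector at the marker nearest the QTL position (same LG)."""
    sites = gmat.sites
    if "lg" not in sites.columns or "pos_cm" not in sites.columns:
        raise ValueError("genotype matrix lacks lg/pos_cm truth metadata")
    on_lg = sites.index[sites["lg"] == qtl.lg]
    if len(on_lg) == 0:
        raise ValueError(f"no markers on LG{qtl.lg} for QTL at {qtl.pos_cm} cM")
    d = (sites.loc[on_lg, "pos_cm"] - qtl.pos_cm).abs()
    i = int(d.idxmin())
    dose = gmat.dosage[i].copy()
    dose[np.isnan(dose)] = np.nanmean(dose)
    return dose


def simulate_phenotypes(
    gmat: GenotypeMatrix,
    qtl: QTLSpec,
    years=(2014, 2015),
    reps=(1, 2),
    seed: int = 0,
    aftermath_years=(2015,),
) -> tuple[pd.DataFrame, dict]:
    """Generate heading-date and aftermath-heading records for a cohort.

    Heading per plant-year-rep record is additive: family mean + sum of
    QTL dosage effects + fixed year effect + N(0, residual_sd^2) noise.
    The aftermath score is a latent Gaussian (its own QTL plus a negative
    coupling to the heading genetic value) cut into the ordinal 1..9 range
    at fixed unit-width thresholds; it is scored only in ``aftermath_years``
    (one year, matching the field design).  Returns (records, truth) where
    truth carries the per-genotype genetic values.
    """
    if len(years) < 1 or len(reps) < 1:
        raise ValueError("need at least one year and one replicate")
    rng = np.random.default_rng(seed)
    n = gmat.n_samples
    g_head = np.zeros(n)
    g_after = np.zeros(n)
    for q in qtl.qtls:
        dose = _qtl_dosage(gmat, q)
        if q.trait == "heading":
            g_head += q.additive_effect * dose
        elif q.trait == "aftermath_latent":
            g_after += q.additive_effect * dose
        else:
            raise ValueError(f"unknown QTL trait {q.trait!r}")
    g_after_total = g_after + qtl.aftermath_coupling * (g_head - g_head.mean())

    records = []
    ids = gmat.samples["sample_id"].to_numpy()
    fams = gmat.samples["family_id"].to_numpy()
    for year in years:
        ye = qtl.year_effects.get(year, 0.0)
        for rep in reps:
            noise = rng.normal(0.0, qtl.residual_sd, size=n)
            heading = qtl.family_mean + g_head + ye + noise
            if year in aftermath_years:
                lat = qtl.aftermath_center + g_after_total + rng.normal(0, qtl.aftermath_sd, n)
                score = np.clip(np.rint(lat), 1, 9).astype(int)
            else:
                score = np.full(n, np.nan)
            for j in range(n):
                records.append(
                    {
                        "genotype_id": ids[j],
                        "family_id": fams[j],
                        "replicate": rep,
                        "year": year,
                        "heading_days": heading[j],
                        "aftermath_score": score[j],
                    }
                )
    truth = {
        "heading_genetic_value": dict(zip(ids, (qtl.family_mean + g_head).tolist(), strict=True)),
        "aftermath_latent_value": dict(zip(ids, g_after_total.tolist(), strict=True)),
        "sigma2_g_realized": float(np.var(g_head, ddof=1)) if n > 1 else 0.0,
        "sigma2_e": float(qtl.residual_sd**2),
        "year_effects": {str(k): v for k, v in qtl.year_effects.items()},
    }
    return pd.DataFrame(records), truth


# ---------------------------------------------------------------------------
# GBS noise


def apply_gbs_noise(
    gmat: GenotypeMatrix,
    missing_rate: float,
    genotype_error_rate: float,
    seed: int,
    flag_errors_low_gq: bool = False,
    good_gq: int = 60,
    error_gq: int = 20,
) -> GenotypeMatrix:
    """Inject GBS-like missingness and genotyping error.

    Each call is independently set missing with ``missing_rate``; each
    surviving call is perturbed to a uniformly chosen *different* dosage
    with ``genotype_error_rate``.  GQ is ``good_gq`` everywhere, except
    that perturbed calls get ``error_gq`` when ``flag_errors_low_gq`` is
    set, so a GQ filter can optionally flag them.
    """
    for name, rate in (("missing_rate", missing_rate), ("genotype_error_rate", genotype_error_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    out = gmat.copy()
    shape = out.dosage.shape
    miss = rng.random(shape) < missing_rate
    err = (rng.random(shape) < genotype_error_rate) & ~miss & ~np.isnan(out.dosage)
    shift = rng.integers(1, 3, size=shape)  # +1 or +2 mod 3 -> always different
    out.dosage[err] = (out.dosage[err] + shift[err]) % 3
    out.dosage[miss] = np.nan
    gq = np.full(shape, float(good_gq))
    if flag_errors_low_gq:
        gq[err] = float(error_gq)
    gq[np.isnan(out.dosage)] = np.nan
    out.gq = gq
    return out


# ---------------------------------------------------------------------------
# Zipper


def make_zipper(
    gmap: pd.DataFrame,
    scaffolds_per_lg: int = 40,
    unanchored_fraction: float = 0.0,
    seed: int = 0,
    bp_per_cm: float = 1_000_000.0,
) -> pd.DataFrame:
    """Scaffold -> (lg, pos_cm) anchoring table consistent with make_loci.

    Each scaffold is anchored at the midpoint of its cM chunk, rounded to
    0.1 cM (zipper tables carry one-decimal genetic positions).  A random
    ``unanchored_fraction`` of scaffolds is omitted, emulating scaffolds
    the zipper could not place.
    """
    if not 0.0 <= unanchored_fraction < 1.0:
        raise ValueError("unanchored_fraction must lie in [0, 1)")
    loci = make_loci(gmap, scaffolds_per_lg=scaffolds_per_lg, bp_per_cm=bp_per_cm)
    rows = []
    for (lg, scaf), grp in loci.groupby(["lg", "scaffold"], sort=True):
        lg_len = gmap.loc[gmap["lg"] == lg, "pos_cm"].max()
        span = max(lg_len, 1e-9) / scaffolds_per_lg
        chunk = int(scaf.rsplit("_", 1)[1])
        rows.append(
            {
                "scaffold": scaf,
                "lg": int(lg),
                "pos_cm": round((chunk + 0.5) * span, 1),
            }
        )
    zipper = pd.DataFrame(rows).sort_values(["lg", "pos_cm"], kind="stable").reset_index(drop=True)
    if unanchored_fraction > 0:
        rng = np.random.default_rng(seed)
        keep = rng.random(len(zipper)) >= unanchored_fraction
        zipper = zipper[keep].reset_index(drop=True)
    return zipper


# ---------------------------------------------------------------------------
# Whole-study generator


#: Family structure of the emulated design: id -> (mean heading days, cross label)
DEFAULT_FAMILIES = {
    "G11": (42.0, "Late x Early"),
    "G12": (48.0, "Inter x Late"),
    "G15": (56.0, "Late x Late"),
    "G16": (57.0, "Late x Late"),
    "G17": (58.0, "Late x Late"),
    "G18": (50.0, "Inter x Inter"),
}

#: Heading QTL on the linkage groups where large-effect heading QTL recur
#: (LG4 and LG7, plus smaller effects on LG2 and LG6); aftermath heading has
#: its own QTL on LG6 plus the negative coupling to heading.
DEFAULT_QTLS = [
    QTL(lg=4, pos_cm=35.0, additive_effect=3.0, trait="heading"),
    QTL(lg=7, pos_cm=45.0, additive_effect=2.5, trait="heading"),
    QTL(lg=2, pos_cm=80.0, additive_effect=2.0, trait="heading"),
    QTL(lg=6, pos_cm=50.0, additive_effect=1.5, trait="heading"),
    QTL(lg=6, pos_cm=45.0, additive_effect=0.8, trait="aftermath_latent"),
]


def simulate_study(config: SimConfig) -> dict:
    """Generate the full synthetic study: genotypes, phenotypes, map, zipper.

    Returns a dict with keys: genotypes (GenotypeMatrix over all families,
    after GBS noise), clean_genotypes (pre-noise), phenotypes (DataFrame),
    gmap, loci, zipper, truth (per-family truth records), config.
    """
    rng = np.random.default_rng(config.seed)
    gmap = make_genetic_map(
        config.n_lgs, config.lg_length_cm, config.n_markers, seed=int(rng.integers(2**31))
    )
    loci = make_loci(gmap, scaffolds_per_lg=config.scaffolds_per_lg, bp_per_cm=config.bp_per_cm)
    zipper = make_zipper(
        gmap,
        scaffolds_per_lg=config.scaffolds_per_lg,
        unanchored_fraction=config.unanchored_scaffold_fraction,
        seed=int(rng.integers(2**31)),
        bp_per_cm=config.bp_per_cm,
    )
    fam_ids = list(DEFAULT_FAMILIES)[: config.n_families]
    if config.n_families > len(fam_ids):
        fam_ids += [f"G{90 + i}" for i in range(config.n_families - len(fam_ids))]

    mats, phenos, truths = [], [], {}
    for fam in fam_ids:
        mean = DEFAULT_FAMILIES.get(fam, (50.0, ""))[0]
        parents = make_parent_pair(
            loci, fam, seed=int(rng.integers(2**31)), cross_mode=config.cross_mode
        )
        fam_mat = simulate_family(
            parents, loci, config.n_offspring_per_family,
            seed=int(rng.integers(2**31)), n_f1=config.n_f1,
        )
        spec = QTLSpec(qtls=list(DEFAULT_QTLS), family_mean=mean)
        ph, truth = simulate_phenotypes(fam_mat, spec, seed=int(rng.integers(2**31)))
        mats.append(fam_mat)
        phenos.append(ph)
        truths[fam] = truth

    clean = GenotypeMatrix(
        sites=mats[0].sites,
        samples=pd.concat([m.samples for m in mats], ignore_index=True),
        dosage=np.concatenate([m.dosage for m in mats], axis=1),
    )
    noisy = apply_gbs_noise(
        clean, config.missing_rate, config.genotype_error_rate, seed=int(rng.integers(2**31))
    )
    return {
        "genotypes": noisy,
        "clean_genotypes": clean,
        "phenotypes": pd.concat(phenos, ignore_index=True),
        "gmap": gmap,
        "loci": loci,
        "zipper": zipper,
        "truth": truths,
        "config": config,
    }
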