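import numpy as np
import pandas as pd
import pytest

from fsibqtl import simdata as sd


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared by read-only tests."""
    cfg = sd.SimConfig(n_markers=600, scaffolds_per_lg=10, seed=3)
    return sd.simulate_study(cfg)


@pytest.fixture()
def f1_testcross_family():
    """A clean (no noise) F1 full-sib family where every locus is hom x het."""
    gmap = sd.make_genetic_map(2, 100.0, 120, seed=9)
    loci = sd.make_loci(gmap, scaffolds_per_lg=10)
    parents = sd.make_parent_pair(
        loci, "FAM", seed=10, p_testcross=1.0, p_hethet=0.0, cross_mode="F1_fullsib"
    )
    fam = sd.simulate_family(parents, loci, 60, seed=11)
    return fam, gmap, loci, parents


def toy_matrix(dosage, scaffold="s1", gq=None, mq=60.0, family="F"):
    """Build a GenotypeMatrix from a plain (sites x samples) dosage array."""
    from fsibqtl.formats import GenotypeMatrix

    dosage = np.asarray(dosage, dtype=float)
    n_sites, n_samples = dosage.shape
    sites = pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos_bp": np.arange(1, n_sites + 1) * 100,
            "ref": "A",
            "alt": "T",
            "mq": mq,
        }
    )
    samples = pd.DataFrame(
        {"sample_id": [f"{family}_{j:03d}" for j in range(n_samples)], "family_id": family}
    )
    return GenotypeMatrix(sites=sites, samples=samples, dosage=dosage, gq=gq)
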