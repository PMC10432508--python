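import numpy as np
import pandas as pd
import pytest

from resistscan.data_model import GenotypeData, SampleManifest
from resistscan.simulate import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20170915)


@pytest.fixture
def small_cohort():
    """40 samples, two full-sib families, one causal locus."""
    config = SimConfig(n_samples=40, n_variants=600, family_sizes=(4, 3),
                       causal_loci=((10, 2.0),), intercept=-1.0, seed=11)
    return simulate_cohort(config)


def make_genotype_data(geno, positions=None, chrom="2R", haplotypes=None):
    geno = np.asarray(geno, dtype=np.int8)
    n_var = geno.shape[1]
    if positions is None:
        positions = np.arange(1, n_var + 1) * 100
    variants = pd.DataFrame({
        "chrom": chrom, "pos": positions, "ref": "A", "alt": "T",
        "accessible": True, "annotation": None, "biallelic": True,
    })
    sample_ids = [f"S{i:04d}" for i in range(geno.shape[0])]
    return GenotypeData(variants, geno, sample_ids, haplotypes)


@pytest.fixture
def toy_manifest(tmp_path):
    rows = []
    for loc in ("Alpha", "Beta"):
        for ins in ("deltamethrin", "PM"):
            for k in range(2):
                ph = "alive" if k == 0 else "dead"
                rows.append((f"{loc[0]}{ins[0]}{k}", loc, "Simland",
                             "gambiae", ins, ph))
    df = pd.DataFrame(rows, columns=["sample_id", "location", "country",
                                     "species", "insecticide", "phenotype"])
    path = tmp_path / "manifest.csv"
    df.to_csv(path, index=False)
    return path
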