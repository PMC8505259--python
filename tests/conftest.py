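import numpy as np
import pandas as pd
import pytest

import polypgas as pg
from polypgas.cohort import Cohort


@pytest.fixture(scope="session")
def small_sim_cohort():
    """A small simulated cohort with one planted locus of each class."""
    cfg = pg.SimConfig(
        n_patients=400, n_controls=400, n_snps=600, seed=17,
        planted_loci=[
            pg.PlantedLocus("polytox", 0.3, 2.0),
            pg.PlantedLocus("disease", 0.3, 2.0),
            pg.PlantedLocus("pleiotropic", 0.3, 2.0),
        ],
    )
    cohort = pg.simulate_phenotypes(pg.simulate_genotypes(cfg), cfg)
    return cfg, cohort


def make_hwe_genotypes(rng, n, freqs):
    """Independent Hardy-Weinberg genotypes at the given allele freqs."""
    freqs = np.asarray(freqs)
    m = freqs.size
    return (
        (rng.random((n, m)) < freqs).astype(np.int8)
        + (rng.random((n, m)) < freqs).astype(np.int8)
    )


def make_cohort(geno, chrom=None, pos=None):
    """Wrap a raw genotype matrix in a Cohort with minimal metadata."""
    n, m = geno.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "id": [f"v{j}" for j in range(m)],
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"S{i}" for i in range(n)],
            "sex": np.ones(n, dtype=np.int8),
            "diagnosis": ["unknown"] * n,
        }
    )
    return Cohort(geno.astype(np.int8), variants, samples)
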