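import numpy as np
import pandas as pd
import pytest

from gpeval.data import GenotypeMatrix, Pedigree
from gpeval.simdata import SimConfig, simulate_dataset


def marker_frame(m, chrom="1"):
    return pd.DataFrame(
        {
            "marker": [f"m{j}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 100,
            "a1": "A",
            "a2": "G",
        }
    )


def geno_from_array(arr, ids=None, chrom="1"):
    arr = np.asarray(arr, dtype=float)
    ids = ids or [f"i{k}" for k in range(arr.shape[0])]
    return GenotypeMatrix(arr, ids, marker_frame(arr.shape[1], chrom=chrom))


@pytest.fixture(scope="session")
def trio_pedigree():
    return Pedigree(
        pd.DataFrame(
            {
                "id": ["s", "d", "o"],
                "sire": ["0", "0", "s"],
                "dam": ["0", "0", "d"],
                "generation": [1, 1, 2],
            }
        )
    )


@pytest.fixture(scope="session")
def small_dataset():
    """~110-animal three-generation dataset with a heritable trait."""
    cfg = SimConfig(
        n_founders=30,
        n_generations=3,
        matings_per_generation=20,
        offspring_per_mating=2,
        n_markers=300,
        n_chromosomes=3,
        h2=0.4,
        seed=7,
    )
    ped, geno, pheno, truth = simulate_dataset(cfg)
    return cfg, ped, geno, pheno, truth
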