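import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import frontload as fl
from frontload.contrasts import build_catalog

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: archetype mix scaled down for fast fixtures
SMALL_ARCHETYPES = {
    "frontloaded": 25,
    "stress_tolerance_up": 5,
    "stress_tolerance_down": 5,
    "relatively_upregulated": 25,
    "opposite": 3,
}


def small_config(seed: int = 11, n_genes: int = 600, **kw) -> fl.SimConfig:
    return fl.SimConfig(
        n_genes=n_genes, archetype_counts=dict(SMALL_ARCHETYPES), seed=seed, **kw
    )


def swap_genotypes(cm: fl.CountMatrix) -> fl.CountMatrix:
    """Relabel T29 samples as T13 and vice versa (counts untouched)."""
    samples = cm.samples.copy()
    samples["genotype"] = samples["genotype"].map({"T29": "T13", "T13": "T29"})
    return fl.CountMatrix(
        counts=cm.counts.copy(), samples=samples, lengths=cm.lengths
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """A 600-gene factorial dataset with planted archetypes (seed 11)."""
    return fl.generate_dataset(small_config())


@pytest.fixture(scope="session")
def planted_catalog(planted_dataset):
    cm, _ = planted_dataset
    return build_catalog(cm)


@pytest.fixture(scope="session")
def null_dataset():
    """400 all-null genes, 3 replicates per cell."""
    cfg = fl.SimConfig(n_genes=400, archetype_counts={}, seed=5)
    return fl.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_counts(matrix, genes=None, samples=None) -> fl.CountMatrix:
    """Hand-built CountMatrix: half of the columns T13_C, half T13_T."""
    arr = np.asarray(matrix)
    n_genes, n_samples = arr.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    half = n_samples // 2
    names = [f"T13_C_r{i+1}" for i in range(half)] + [
        f"T13_T_r{i+1}" for i in range(n_samples - half)
    ]
    samples_df = pd.DataFrame(
        {
            "genotype": ["T13"] * n_samples,
            "condition": ["C"] * half + ["T"] * (n_samples - half),
            "replicate": list(range(1, half + 1))
            + list(range(1, n_samples - half + 1)),
        },
        index=pd.Index(names, name="sample"),
    )
    return fl.CountMatrix(
        counts=pd.DataFrame(arr, index=genes, columns=names), samples=samples_df
    )
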