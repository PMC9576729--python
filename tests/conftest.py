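import numpy as np
import pandas as pd
import pytest

from celldecon import SimulationConfig
from celldecon.pipeline import BundleBuildConfig, build_profile_bundle
from celldecon.simulate import simulate_reference_collection
from celldecon.types import CellTypeProfile, ProfileSet


@pytest.fixture(scope="session")
def small_collection():
    """3 datasets x 4 cell types with planted markers and batch effects."""
    config = SimulationConfig(
        n_datasets=3,
        cell_types=("astro", "neuron", "oligo", "micro"),
        n_genes=600,
        n_signature_genes_per_type=30,
        signature_log2fc=2.5,
        nb_dispersion=0.3,
        batch_gene_sigma=0.3,
        cells_per_type=(100, 150),
        depth_per_cell=(2000, 5000),
        seed=11,
    )
    refs, truth = simulate_reference_collection(config)
    return refs, truth, config


@pytest.fixture(scope="session")
def small_bundle(small_collection):
    """A trained bundle built from the small synthetic collection."""
    refs, _, _ = small_collection
    config = BundleBuildConfig(
        replicates_per_type=3,
        mixed_per_dataset=10,
        max_sets=60,
        min_genes=10,
        max_genes=40,
        seed=11,
    )
    return build_profile_bundle(refs, config)


def make_toy_profile_set(
    n_genes: int = 30,
    cell_types: tuple = ("A", "B", "C"),
    seed: int = 0,
    set_id: str = "toy",
    gene_prefix: str = "g",
) -> ProfileSet:
    """A noiseless random profile set normalized to one million."""
    rng = np.random.default_rng(seed)
    genes = [f"{gene_prefix}{i}" for i in range(n_genes)]
    profiles = {}
    block = n_genes // len(cell_types)
    for k, ct in enumerate(cell_types):
        v = rng.uniform(1.0, 10.0, size=n_genes)
        v[k * block : (k + 1) * block] *= 20.0  # distinct high-expression block
        v = v / v.sum() * 1e6
        profiles[ct] = CellTypeProfile(
            cell_type=ct,
            values=pd.Series(v, index=genes),
            profile_genes=genes[k * block : (k + 1) * block],
            source=("toy", k),
        )
    return ProfileSet(set_id=set_id, profiles=profiles)
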