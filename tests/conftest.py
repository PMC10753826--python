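import numpy as np
import pandas as pd
import pytest

from morelbiome.amplicon import RelAbundanceTable
from morelbiome.simulate import (
    CommunitySimConfig,
    PangenomeSimConfig,
    generate_community,
    generate_pangenome,
)


def make_rel(values, feature_ids=None, sample_ids=None) -> RelAbundanceTable:
    """Build a RelAbundanceTable from a features x samples array."""
    arr = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"t{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    return RelAbundanceTable(pd.DataFrame(arr, index=feature_ids, columns=sample_ids))


def random_rel(rng, n_taxa, n_samples) -> RelAbundanceTable:
    """Random sparse compositional table (some exact zeros, columns sum to 1)."""
    raw = rng.random((n_taxa, n_samples))
    raw[rng.random((n_taxa, n_samples)) < 0.3] = 0.0
    empty = raw.sum(axis=0) == 0
    raw[0, empty] = 1.0
    return make_rel(raw / raw.sum(axis=0))


def brute_force_core(rel, p, d):
    """Independent oracle: literal enumeration over taxa and samples."""
    members = {}
    n = len(rel.sample_ids)
    for taxon in rel.feature_ids:
        hits = sum(1 for s in rel.sample_ids if rel.values.at[taxon, s] > d)
        if hits / n >= p:
            members[taxon] = hits / n
    return members


@pytest.fixture(scope="session")
def community():
    """One default synthetic survey (counts, taxonomy, metadata)."""
    return generate_community(CommunitySimConfig(seed=11))


@pytest.fixture(scope="session")
def small_pangenome():
    """3 genomes, 5 single-copy core clusters, 2 unique clusters per genome."""
    config = PangenomeSimConfig(
        n_genomes=3,
        n_core_clusters=5,
        n_unique_clusters_per_genome=2,
        group_specific=(),
        n_modules=4,
        seed=5,
    )
    return config, generate_pangenome(config)
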