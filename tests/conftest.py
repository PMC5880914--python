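import numpy as np
import pandas as pd
import pytest

from elevassembly import (
    GradientScenario,
    GradientSections,
    OtuTable,
    SampleMetadata,
    generate_community,
    generate_metadata,
)
from elevassembly.containers import DistanceMatrix


@pytest.fixture(scope="session")
def small_scenario() -> GradientScenario:
    """Compact transect: 6 sites x 4 samples, 200 OTUs, strong pH filter."""
    return GradientScenario(
        n_sites=6, samples_per_site=4, n_otus=200, sequencing_depth=2000, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    metadata = generate_metadata(small_scenario)
    table = generate_community(small_scenario, metadata)
    sections = GradientSections.from_metadata(metadata)
    return table, metadata, sections


def random_otu_table(rng: np.random.Generator, n_samples=8, n_otus=30, density=0.5) -> OtuTable:
    counts = rng.poisson(3, size=(n_samples, n_otus))
    counts *= rng.random((n_samples, n_otus)) < density
    counts[counts.sum(axis=1) == 0, 0] = 1  # avoid empty samples
    return OtuTable(
        [f"s{i}" for i in range(n_samples)],
        [f"o{j}" for j in range(n_otus)],
        counts,
    )


def euclidean_dm(points: np.ndarray, prefix="s") -> DistanceMatrix:
    from scipy.spatial.distance import pdist, squareform

    ids = [f"{prefix}{i}" for i in range(points.shape[0])]
    return DistanceMatrix(ids, squareform(pdist(points)))
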