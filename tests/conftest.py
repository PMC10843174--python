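import numpy as np
import pytest

from nucphase.synthetic import (
    ArchetypeSpec,
    SimulationConfig,
    generate_profiles,
    two_archetype_config,
)


@pytest.fixture(scope="session")
def two_archetype_data():
    """Canonical two-archetype set (opposite downstream amplitude trends)."""
    config = two_archetype_config(n_genes=200, seed=11)
    profiles, labels, lengths = generate_profiles(config)
    return config, profiles, labels, lengths


@pytest.fixture(scope="session")
def large_gene_two_archetype_data(two_archetype_data):
    """Large-gene subset of the canonical set (phasing fills the window)."""
    _, profiles, labels, lengths = two_archetype_data
    mask = lengths > 1000
    return profiles.subset(mask), labels[mask], lengths[mask]


@pytest.fixture(scope="session")
def noiseless_single_archetype():
    config = SimulationConfig(
        n_genes=20,
        archetypes=(ArchetypeSpec(),),
        mixture_weights=(1.0,),
        gene_length_distribution=("constant", {"length": 2000}),
        noise_sd=0.0,
        seed=3,
    )
    profiles, labels, lengths = generate_profiles(config)
    return profiles, labels, lengths


def rand_profiles(n_genes, rng, base=1.0):
    """Random smooth-ish non-negative profiles for oracle tests."""
    from nucphase.profile_io import WINDOW_LENGTH

    t = np.arange(WINDOW_LENGTH)
    rows = []
    for _ in range(n_genes):
        row = base + 0.5 * np.sin(2 * np.pi * t / rng.uniform(150, 220) + rng.uniform(0, 6))
        row += rng.normal(0, 0.1, WINDOW_LENGTH)
        rows.append(np.clip(row, 0, None))
    return np.vstack(rows)
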