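import numpy as np
import pytest

from snppanel import (
    GenotypeMatrix,
    Population,
    SampleRecord,
    SimConfig,
    VariantRecord,
    simulate_panel,
)


def make_matrix(calls, positions=None, chroms=None, populations=None, ids=None):
    """Small hand-built GenotypeMatrix; calls is samples x variants."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_variants = calls.shape
    positions = positions or [100 * (j + 1) for j in range(n_variants)]
    chroms = chroms or ["chr01"] * n_variants
    ids = ids or [f"v{j}" for j in range(n_variants)]
    populations = populations or [Population.UNKNOWN] * n_samples
    variants = [
        VariantRecord(ids[j], chroms[j], positions[j], "A", "G") for j in range(n_variants)
    ]
    samples = [
        SampleRecord(f"s{i}", Population(populations[i]) if not isinstance(populations[i], Population) else populations[i])
        for i in range(n_samples)
    ]
    return GenotypeMatrix(variants=variants, samples=samples, calls=calls)


@pytest.fixture
def two_pop_matrix():
    """4 temperate + 4 tropical samples, 3 variants, no missing data."""
    calls = np.array(
        [
            [2, 2, 0],
            [2, 1, 0],
            [1, 2, 0],
            [2, 2, 2],
            [0, 0, 0],
            [0, 0, 2],
            [0, 1, 0],
            [0, 0, 0],
        ]
    )
    pops = [Population.TEMPERATE] * 4 + [Population.TROPICAL] * 4
    return make_matrix(calls, populations=pops)


@pytest.fixture
def small_sim():
    cfg = SimConfig(
        n_temperate=40,
        n_tropical=40,
        n_variants=400,
        n_chromosomes=4,
        chrom_length=1_000_000,
        target_fst=0.15,
        seed=42,
    )
    matrix, truth = simulate_panel(cfg)
    return cfg, matrix, truth
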