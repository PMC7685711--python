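import numpy as np
import pandas as pd
import pytest

from viropop import CohortConfig, GenotypeMatrix, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic survey (333 flies, 4 populations)."""
    return generate_cohort(CohortConfig(seed=2))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced two-population cohort for fast association tests."""
    config = CohortConfig(
        n_populations=2,
        samples_per_population=(60, 60),
        infection_rate_per_population=(0.7, 0.8),
        high_type_freq_per_population=(0.5, 0.6),
        n_background_private=5,
        n_background_shared=4,
        n_noise_loci=10,
        seed=7,
    )
    return generate_cohort(config)


def matrix_from_consensus(calls: np.ndarray, positions=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix straight from a 0/1 consensus array."""
    calls = np.asarray(calls, dtype=float)
    n, L = calls.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(L)]
    ids = [f"L{j + 1}" for j in range(L)]
    loci = pd.DataFrame({
        "position": positions,
        "annotation": ["intergenic"] * L,
        "gene": [f"g{j}" for j in range(L)],
        "focal": [False] * L,
        "focal_order": [np.nan] * L,
    }, index=pd.Index(ids, name="locus_id"))
    freq = pd.DataFrame(calls,
                        index=pd.Index([f"s{i + 1}" for i in range(n)],
                                       name="sample_id"),
                        columns=loci.index)
    return GenotypeMatrix(freq=freq, loci=loci)
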