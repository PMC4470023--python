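import numpy as np
import pytest

from msatpop import (
    GenotypeDataset,
    SimConfig,
    allele_frequencies,
    simulate_breeds,
)


def make_dataset(genotypes: dict[str, list[tuple]], loci: list[str] | None = None):
    """Build a GenotypeDataset from {breed: [((a, b), (c, d), ...), ...]}.

    Each individual is a tuple of per-locus allele pairs; (0, 0) is missing.
    """
    individuals, breed_of, rows = [], [], []
    n_loci = None
    for breed, inds in genotypes.items():
        for k, calls in enumerate(inds):
            individuals.append(f"{breed}_{k + 1}")
            breed_of.append(breed)
            rows.append(list(calls))
            n_loci = len(calls)
    loci = loci or [f"L{l + 1}" for l in range(n_loci)]
    return GenotypeDataset(
        individuals, np.asarray(breed_of, dtype=object), loci,
        np.asarray(rows, dtype=np.int32),
    )


@pytest.fixture
def toy_two_breeds():
    """Two breeds, one locus: {A/A, A/B} and {B/B}."""
    return make_dataset({"X": [((1, 1),), ((1, 2),)], "Y": [((2, 2),)]})


@pytest.fixture(scope="session")
def small_sim():
    """Six moderately drifted breeds, 8 loci — a general-purpose dataset."""
    cfg = SimConfig(
        n_breeds=6, n_loci=8, alleles_per_locus=(4, 10),
        sample_sizes=[30] * 6, divergence=[0.10] * 6,
        missing_rate=0.05, seed=20240915,
    )
    return simulate_breeds(cfg)


@pytest.fixture(scope="session")
def small_sim_freq(small_sim):
    ds, _ = small_sim
    return allele_frequencies(ds)
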