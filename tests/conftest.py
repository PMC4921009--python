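import numpy as np
import pandas as pd
import pytest

from haplotrace import PhasedPanel


def build_panel(alleles, populations, generations, ids=None):
    """Assemble a PhasedPanel from a strand matrix and per-animal labels."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_animals = alleles.shape[0] // 2
    animals = pd.DataFrame({
        "id": ids if ids is not None else np.arange(1, n_animals + 1),
        "population": populations,
        "generation": generations,
        "sex": np.zeros(n_animals, dtype=int),
    })
    return PhasedPanel(alleles=alleles, animals=animals)


def random_panel(rng, n_animals, n_snps, populations=("P",), n_generations=2):
    """Random phased panel with animals spread over populations/generations."""
    alleles = rng.integers(0, 2, size=(2 * n_animals, n_snps), dtype=np.uint8)
    pops = [populations[i % len(populations)] for i in range(n_animals)]
    gens = [(i // len(populations)) % n_generations for i in range(n_animals)]
    return build_panel(alleles, pops, gens)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


@pytest.fixture
def toy_panel(rng):
    """20 strands x 3 cores of 5 SNPs, one population, three generations."""
    return random_panel(rng, n_animals=10, n_snps=15, n_generations=3)
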