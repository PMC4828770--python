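import numpy as np
import pytest

from radmix import GenotypeMatrix, PopulationMap, QuartetConfig
from radmix.simulate import ScenarioParams, simulate_frequency_scenario, simulate_mosaic_hybrids


def matrix_from_genotypes(genotypes: dict[str, list[str]]) -> GenotypeMatrix:
    """Build a matrix from {individual: ["A/G", "C/C", ...]} (loci in list order)."""
    individuals = list(genotypes)
    n_loci = len(next(iter(genotypes.values())))
    labels = np.full((n_loci, len(individuals), 2), ".", dtype=object)
    for i, ind in enumerate(individuals):
        for l, call in enumerate(genotypes[ind]):
            a, _, b = call.partition("/")
            labels[l, i, 0], labels[l, i, 1] = a, b
    locus_ids = [f"L{l + 1}:1" for l in range(n_loci)]
    return GenotypeMatrix.from_labels(locus_ids, individuals, labels)


@pytest.fixture(scope="session")
def freq_dataset():
    """Moderate zero-gene-flow frequency-mode scenario shared across tests."""
    params = ScenarioParams(n_loci=1000, f=0.0, seed=7)
    return simulate_frequency_scenario(params)


@pytest.fixture(scope="session")
def mosaic_dataset():
    """Mosaic scenario with a 20% pulse and a few generations of mating."""
    params = ScenarioParams(n_loci=1500, mode="mosaic", f=0.2, n_generations=5, seed=11)
    return simulate_mosaic_hybrids(params)


@pytest.fixture
def default_quartet():
    return QuartetConfig(p1="P1", p3="P3", outgroup="OUT", p2_candidates=["H"])
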