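import numpy as np
import pytest

from sorgwue.io_formats import GenotypeMatrix, MarkerInfo
from sorgwue.synthetic_data import SimulationConfig, simulate_field_phenotypes, simulate_genotypes


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced-scale panel used by most integration-style tests."""
    return SimulationConfig(n_accessions=120, n_markers=400, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    G, truth = simulate_genotypes(small_config)
    pheno, truth = simulate_field_phenotypes(G, truth, small_config)
    return G, truth, pheno


def make_genotypes(dosages, chroms=None, positions=None, refs=None, alts=None,
                   ids=None) -> GenotypeMatrix:
    """Hand-build a GenotypeMatrix from a dosage array."""
    dosages = np.asarray(dosages)
    n_acc, n_mark = dosages.shape
    chroms = chroms or ["1"] * n_mark
    positions = positions or list(range(100, 100 + 100 * n_mark, 100))
    refs = refs or ["A"] * n_mark
    alts = alts or ["T"] * n_mark
    ids = ids or [f"M{j}" for j in range(n_mark)]
    markers = [
        MarkerInfo(ids[j], chroms[j], positions[j], refs[j], alts[j])
        for j in range(n_mark)
    ]
    return GenotypeMatrix([f"A{i}" for i in range(n_acc)], markers, dosages)
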