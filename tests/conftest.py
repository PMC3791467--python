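import numpy as np
import pandas as pd
import pytest

from cytoqtl.data import GenotypeMatrix
from cytoqtl.simulate import (
    SimulationConfig,
    simulate_map,
    simulate_ril_genotypes,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        seed=11,
        n_lines=120,
        cyto_counts=(50, 70),
        n_chromosomes=2,
        chrom_lengths=(80.0, 80.0),
        n_markers=40,
        n_metabolites=12,
    )


@pytest.fixture(scope="session")
def small_map(small_cfg):
    return simulate_map(small_cfg)


@pytest.fixture(scope="session")
def small_geno(small_cfg, small_map):
    return simulate_ril_genotypes(small_map, small_cfg)


@pytest.fixture(scope="session")
def desk_cfg():
    """Default desk-scale scenario: 240 lines (100 Kas / 140 Tsu), 5 x 100 cM."""
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def desk_map(desk_cfg):
    return simulate_map(desk_cfg)


@pytest.fixture(scope="session")
def desk_geno(desk_cfg, desk_map):
    return simulate_ril_genotypes(desk_map, desk_cfg)


def balanced_factorial_genotypes(markers, reps=30):
    """All homozygous combinations of the loci (plus cytoplasm), replicated.

    Gives an exactly orthogonal design for tests needing deterministic
    model algebra.
    """
    import itertools

    combos = np.array(list(itertools.product([1, -1], repeat=len(markers) + 1)))
    rep = np.repeat(combos, reps, axis=0)
    lines = pd.Index([f"L{i:04d}" for i in range(len(rep))], name="line")
    alleles = pd.DataFrame(
        rep[:, :-1], index=lines, columns=markers, dtype=np.int8
    )
    cyto = pd.Series(rep[:, -1], index=lines, name="cytoplasm", dtype=np.int8)
    return GenotypeMatrix(alleles, cyto)
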