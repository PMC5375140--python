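import numpy as np
import pandas as pd
import pytest

from mitoscan.containers import GenotypeMatrix


def make_gm(dosages, scaffolds=None, positions=None, mt=None, populations=None):
    """Small hand-specified GenotypeMatrix for unit tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, L = dosages.shape
    scaffolds = scaffolds if scaffolds is not None else ["s1"] * L
    positions = positions if positions is not None else list(range(100, 100 + 200 * L, 200))
    mt = mt if mt is not None else ["north"] * (n // 2) + ["south"] * (n - n // 2)
    loci = pd.DataFrame(
        {
            "locus_id": [f"l{j}" for j in range(L)],
            "scaffold": scaffolds,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"i{i}" for i in range(n)],
            "mt_haplotype": mt,
            "population": populations if populations is not None else "P",
        }
    )
    return GenotypeMatrix(dosages=dosages, loci=loci, samples=samples)


@pytest.fixture
def toy_gm():
    """8 individuals x 4 loci, two mt groups, one missing call."""
    d = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 2, 0],
            [0, 0, 1, 0],
            [2, 1, 0, 0],
            [2, 2, 0, 1],
            [1, 2, 0, np.nan],
            [2, 1, 1, 0],
            [2, 2, 0, 0],
        ]
    )
    return make_gm(d)


@pytest.fixture(scope="session")
def null_cohort():
    """Pure-null cohort: no planted loci, no mt-group differences."""
    from mitoscan.simulate import SimScenario, simulate_genotypes

    sc = SimScenario(
        n_individuals=80,
        n_loci=600,
        n_planted=0,
        background_delta=0.0,
        planted_delta=0.0,
        seed=101,
    )
    gm, truth = simulate_genotypes(sc)
    return gm, truth
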