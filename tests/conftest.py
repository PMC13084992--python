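import numpy as np
import pandas as pd
import pytest

from lousepop.genio import GenotypeMatrix, PopulationMap


def make_gm(genotypes, qual=None, dp=None, gq=None, positions=None, scaffold="s1"):
    """Build a GenotypeMatrix from a (N, S) dosage array with defaults."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, s = genotypes.shape
    if positions is None:
        positions = np.arange(1, s + 1)
    sites = pd.DataFrame(
        {
            "scaffold": [scaffold] * s if isinstance(scaffold, str) else scaffold,
            "pos": positions,
            "ref": ["A"] * s,
            "alt": ["C"] * s,
            "qual": np.full(s, 60.0) if qual is None else np.asarray(qual, dtype=float),
        }
    )
    individuals = [f"ind{i}" for i in range(n)]
    dp = None if dp is None else np.asarray(dp, dtype=np.int32)
    gq = None if gq is None else np.asarray(gq, dtype=np.int32)
    return GenotypeMatrix(individuals, sites, genotypes, dp, gq)


@pytest.fixture
def toy_gm():
    """3 populations x 2 individuals, 6 hand-readable sites."""
    genotypes = np.array(
        [
            # sites:  1  2  3  4  5  6
            [0, 1, 2, 0, 2, 1],  # popA
            [0, 1, 2, 0, 2, 0],  # popA
            [0, 0, 0, 2, 2, 1],  # popB
            [0, 0, 0, 2, 2, 1],  # popB
            [0, 0, 2, 1, 0, 1],  # popC
            [0, 0, 2, 1, 0, 1],  # popC
        ],
        dtype=np.int8,
    )
    return make_gm(genotypes)


@pytest.fixture
def toy_popmap():
    return PopulationMap(
        {
            "ind0": "popA",
            "ind1": "popA",
            "ind2": "popB",
            "ind3": "popB",
            "ind4": "popC",
            "ind5": "popC",
        }
    )
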