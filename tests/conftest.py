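import numpy as np
import pytest

from coalpop.datatypes import GenotypeMatrix, PopulationPartition, SequenceAlignment
from coalpop.synth import make_ashw_fixture


@pytest.fixture(scope="session")
def ashw():
    """Screened synthetic study-scale fixture (47 individuals)."""
    return make_ashw_fixture(seed=0)


@pytest.fixture(scope="session")
def ashw_raw():
    """Raw fixture with planted duplicates and failed samples (67)."""
    return make_ashw_fixture(seed=0, raw=True)


@pytest.fixture
def tiny_alignment():
    return SequenceAlignment(
        sample_ids=["a", "b", "c", "d"],
        sequences=["AAAA", "AAAT", "AATT", "AAAA"],
    )


@pytest.fixture
def one_pop():
    def _make(sample_ids, label="p1"):
        return PopulationPartition({s: label for s in sample_ids})

    return _make


def make_gm(genos, locus_names=None, motifs=None):
    """Genotype matrix from a nested list [[(a,b) per locus] per ind]."""
    genos = np.array(genos, dtype=int)
    n, L = genos.shape[0], genos.shape[1]
    return GenotypeMatrix(
        sample_ids=[f"i{k}" for k in range(n)],
        locus_names=locus_names or [f"L{j}" for j in range(L)],
        motif_lengths=np.array(motifs) if motifs else np.full(L, 2),
        alleles=genos,
    )
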