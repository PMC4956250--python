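import numpy as np
import pytest

from msatpop.dataset import GenotypeDataset, Locus, PopulationInfo
from msatpop import synthetic as syn


def make_dataset(genotypes_by_pop, motif_length=2, locus_names=None):
    """Build a small dataset from {pop_id: [[(a, b), ...] per individual]}.

    Each individual is a list of (allele_a, allele_b) tuples, one per locus.
    """
    pops = []
    rows = []
    pop_index = []
    n_loci = None
    for k, (pid, inds) in enumerate(genotypes_by_pop.items()):
        pops.append(PopulationInfo(id=pid, n=len(inds)))
        for ind in inds:
            if n_loci is None:
                n_loci = len(ind)
            rows.append([list(g) for g in ind])
            pop_index.append(k)
    names = locus_names or [f"L{j + 1:02d}" for j in range(n_loci)]
    loci = [Locus(nm, motif_length) for nm in names]
    calls = np.asarray(rows, dtype=np.int64)
    return GenotypeDataset(loci, pops, calls, np.asarray(pop_index))


@pytest.fixture(scope="session")
def island_dataset():
    """Medium island-model dataset shared by several statistic tests."""
    spec = syn.GeneratorSpec(
        n_populations=4, n_individuals=30, n_loci=6, fst=0.15, seed=101
    )
    ds, truth = syn.generate(spec)
    return ds, truth


@pytest.fixture(scope="session")
def paper_fixture():
    ds, truth = syn.paper_shaped_fixture(seed=7)
    return ds, truth
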