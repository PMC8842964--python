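import numpy as np
import pytest

from pangotrace.genodata import MISSING, GenotypeDataset


def make_dataset(genotypes, populations=None, site_class=None, loci=None,
                 sample_ids=None, coords=None):
    """Build a small GenotypeDataset from a list of per-sample genotype lists.

    ``genotypes[i]`` is a list of (a, b) tuples or None (missing) per locus.
    """
    n = len(genotypes)
    L = len(genotypes[0])
    calls = np.full((n, L, 2), MISSING, dtype=np.int64)
    for i, row in enumerate(genotypes):
        for j, g in enumerate(row):
            if g is not None:
                calls[i, j] = sorted(g)
    return GenotypeDataset(
        sample_ids=sample_ids or [f"S{i + 1}" for i in range(n)],
        locus_names=loci or [f"L{j + 1}" for j in range(L)],
        calls=calls,
        population=populations or ["P1"] * n,
        site_class=site_class or ["forest"] * n,
        coords=coords,
    )


@pytest.fixture
def wc_oracle_dataset():
    """Two populations, pop1 {A/A, A/B}, pop2 {B/B, B/B}; hand-derived theta = 2/3."""
    return make_dataset(
        [[(1, 1)], [(1, 2)], [(2, 2)], [(2, 2)]],
        populations=["p1", "p1", "p2", "p2"],
        sample_ids=["a", "b", "c", "d"],
    )


@pytest.fixture(scope="session")
def study_scale():
    """A study-scale synthetic dataset shared across tests (seeded)."""
    from pangotrace.synth import default_study_config, simulate_dataset

    ds, truth = simulate_dataset(default_study_config(11))
    return ds, truth
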