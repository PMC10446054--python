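import warnings

import numpy as np
import pytest

import pedconnect as pc


@pytest.fixture(scope="session")
def small_sim():
    """One moderate simulated dataset shared across tests (seeded)."""
    cfg = pc.SimConfig(rng_seed=7, founders_per_patch=10, n_years=10, m_pollen=0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        genotypes, records, truth = pc.simulate(cfg)
    return cfg, genotypes, pc.records_to_frame(records), truth


@pytest.fixture(scope="session")
def small_assignment(small_sim):
    """Parentage assignment on the shared simulated dataset."""
    _, genotypes, records, truth = small_sim
    result = pc.assign_parents(genotypes, records, pc.AssignmentConfig())
    return result


@pytest.fixture(scope="session")
def small_pedigree(small_sim, small_assignment):
    _, _, records, _ = small_sim
    return pc.PedigreeGraph.from_assignments(small_assignment, records)


def make_table(rows, loci=None):
    """Hand-build a GenotypeTable from {id: [(a, b) or None, ...]}."""
    ids = list(rows)
    n_loci = len(next(iter(rows.values())))
    loci = loci or [f"L{j + 1}" for j in range(n_loci)]
    alleles = np.full((len(ids), n_loci, 2), pc.MISSING, dtype=np.int32)
    for i, ind in enumerate(ids):
        for j, cell in enumerate(rows[ind]):
            if cell is not None:
                alleles[i, j] = cell
    return pc.GenotypeTable(ids=ids, loci=loci, alleles=alleles)
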