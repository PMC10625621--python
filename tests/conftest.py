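import warnings

import pytest

import netcontrast as nc


@pytest.fixture(scope="session")
def small_dataset():
    """One scaled-down synthetic dataset shared across tests."""
    params = nc.GeneratorParams(
        n_genes=600, n_ndd_genes=150, n_ndd_mutations=300, n_pathways=30,
        rng_seed=11,
    )
    return nc.generate_all(params)


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the default study conditions."""
    return nc.generate_all(nc.GeneratorParams(rng_seed=1))


@pytest.fixture()
def no_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def make_catalog(rows, name="test"):
    """rows: (sample, gene, change[, phenotype[, pathogenicity]])."""
    records = []
    for row in rows:
        sample, gene, change = row[:3]
        pheno = row[3] if len(row) > 3 else None
        patho = row[4] if len(row) > 4 else None
        records.append(nc.MutationRecord(sample, gene, change, pheno, patho))
    return nc.MutationCatalog(name, records)
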