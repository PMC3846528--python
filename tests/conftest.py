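import pytest

from symtrophy import pathway_model as pm


@pytest.fixture(scope="session")
def pathways():
    return pm.default_pathways()


@pytest.fixture(scope="session")
def genomes():
    return pm.default_genomes()


@pytest.fixture(scope="session")
def genomes_by_name(genomes):
    return {g.organism: g for g in genomes}


@pytest.fixture(scope="session")
def lysine_pathway(pathways):
    return next(p for p in pathways if p.id == "lysine_dap")


@pytest.fixture(scope="session")
def arg_pathway(pathways):
    return next(p for p in pathways if p.id == "arg_orn")
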