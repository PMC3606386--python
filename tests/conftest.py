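import pytest

from lgt_hunter.scoring import nucleotide_default, protein_default


@pytest.fixture(scope="session")
def dna_scheme():
    return nucleotide_default()


@pytest.fixture(scope="session")
def prot_scheme():
    return protein_default()


@pytest.fixture(scope="session")
def acceptance_assembly():
    """The standard seed-7 screening fixture (assembly, bacterial panel,
    animal panel, ground truth, recipe)."""
    from lgt_hunter.simulate import make_acceptance_assembly

    return make_acceptance_assembly(seed=7)


@pytest.fixture(scope="session")
def acceptance_screen(acceptance_assembly, dna_scheme):
    """Screen results on the seed-7 fixture, shared across tests."""
    from lgt_hunter.screen import screen

    assembly, bacterial_db, animal_db, truth, recipe = acceptance_assembly
    return screen(assembly, bacterial_db, animal_db, dna_scheme), truth
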