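import pytest
from hypothesis import settings

from karyomorph import datasets

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def template():
    """Bundled 18-type X. pygmaeus karyotype template."""
    return datasets.load_pygmaeus_template()


@pytest.fixture(scope="session")
def arm_ratios():
    return datasets.load_reference_arm_ratios()


@pytest.fixture(scope="session")
def reference_map():
    return datasets.load_marker_map("tropicalis")


@pytest.fixture(scope="session")
def pygmaeus_map():
    return datasets.load_marker_map("pygmaeus")


@pytest.fixture(scope="session")
def mellotropicalis_map():
    return datasets.load_marker_map("mellotropicalis")


@pytest.fixture(scope="session")
def species_tree():
    return datasets.load_species_tree()


@pytest.fixture(scope="session")
def nor_states():
    return datasets.load_nor_states()


@pytest.fixture(scope="session")
def rdna_signals():
    return datasets.load_rdna_signals()
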