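import pytest

from mtanno import load_default_bundle
from mtanno.fixtures import generate_toy_genome, generate_variants


@pytest.fixture(scope="session")
def bundle():
    """The packaged human rCRS annotation bundle."""
    return load_default_bundle()


@pytest.fixture(scope="session")
def toy():
    """A deterministic toy genome with full ground truth."""
    return generate_toy_genome(seed=7, n_genes=3, codons_per_gene=9)


@pytest.fixture(scope="session")
def toy_bundle(toy):
    return toy.bundle()


@pytest.fixture()
def toy_bundle_dir(toy, tmp_path):
    """The toy bundle serialized through the production writer."""
    path = tmp_path / "bundle"
    truth_dir = path
    toy.save_bundle(truth_dir)
    return truth_dir


@pytest.fixture(scope="session")
def toy_expectations(toy):
    return generate_variants(seed=8, truth=toy, n=25)
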