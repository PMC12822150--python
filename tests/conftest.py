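import pytest

from genesym.fixtures import FixtureConfig, generate, preset
from genesym.loci import LocusCategory


@pytest.fixture(scope="session")
def exemplars():
    return preset("ambiguity_exemplars")


@pytest.fixture(scope="session")
def loci_examples():
    return preset("multiplied_loci")


@pytest.fixture(scope="session")
def trial_tables():
    return preset("update_trial")


@pytest.fixture(scope="session")
def hras():
    return preset("ras_synonyms_rat")


@pytest.fixture
def make_bundle():
    """Factory for seeded synthetic bundles with every structure planted."""

    def _make(seed=0, n_genes=200, **kw):
        kw.setdefault(
            "n_per_locus_category", {cat: 1 for cat in LocusCategory}
        )
        return generate(FixtureConfig(seed=seed, n_genes=n_genes, **kw))

    return _make
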