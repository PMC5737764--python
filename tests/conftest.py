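import pytest

from moipred.annotate import AnnotationConfig
from moipred.fixtures import FixtureConfig, generate_fixture_set


def small_config(**overrides) -> FixtureConfig:
    base = dict(
        n_genes={"benign": 8, "dominant": 6, "recessive": 8},
        n_variants={"benign": 24, "dominant": 18, "recessive": 24},
        delta=3.0,
        missingness=0.05,
    )
    base.update(overrides)
    return FixtureConfig(**base)


@pytest.fixture(scope="session")
def small_fixture_set():
    """A small but complete synthetic study shared by read-only tests."""
    return generate_fixture_set(small_config(), seed=101)


@pytest.fixture(scope="session")
def small_pools(small_fixture_set):
    return small_fixture_set.labeled_pools()


@pytest.fixture(scope="session")
def catalogue():
    return AnnotationConfig().catalogue()
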