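import pytest

from haisurv import (
    CohortSpec,
    default_catalog,
    default_lexicon,
    default_registry,
    default_rule_base,
    generate_cohort,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def rule_base():
    return default_rule_base()


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort whose infections each satisfy one packaged rule."""
    spec = CohortSpec(seed=202, n_patients=200, prevalence=0.05,
                      dropout_q=0.0, note_noise=0.0)
    return generate_cohort(spec)
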