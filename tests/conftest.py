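import pytest

from mitocomp.synthetic import GenomeSpec, default_survey_spec, make_mitogenome, \
    make_population


@pytest.fixture(scope="session")
def default_genome():
    """A planthopper-like synthetic mitogenome (delphacid order, AT 0.77)."""
    return make_mitogenome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def survey_spec():
    return default_survey_spec(seed=0)


@pytest.fixture(scope="session")
def survey_population(survey_spec):
    return make_population(survey_spec)
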