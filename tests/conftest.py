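import pytest

from karyoevol import fixtures


@pytest.fixture(scope="session")
def case():
    """The littorinid/scallop case study encoded from the published maps."""
    return fixtures.case_study()


@pytest.fixture(scope="session")
def case_sim():
    """Synthetic genomes evolved along the case-study event scripts."""
    return fixtures.simulate_case(seed=11)
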