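import pytest

from leukotype.genome import default_genome
from leukotype.pipeline import run
from leukotype.simulate import generate_cohort, paper_roster_config

ROSTER_SEED = 1


@pytest.fixture(scope="session")
def reference():
    return default_genome()


@pytest.fixture(scope="session")
def roster(reference):
    """The printed-roster preset cohort (57 cases) used by cohort-level tests."""
    return generate_cohort(paper_roster_config(ROSTER_SEED), reference)


@pytest.fixture(scope="session")
def report(roster, reference):
    return run(roster, reference=reference)
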