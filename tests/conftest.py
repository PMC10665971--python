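import warnings

import pytest

from rule48 import load_paper_fixture, paper_run_config, run_pipeline, tune_sigma

warnings.filterwarnings("ignore", message="ArviZ is undergoing")


@pytest.fixture(scope="session")
def paper_fixture():
    counts, cohorts = load_paper_fixture()
    return counts, cohorts


@pytest.fixture(scope="session")
def paper_counts(paper_fixture):
    return paper_fixture[0]


@pytest.fixture(scope="session")
def paper_cohorts(paper_fixture):
    return paper_fixture[1]


@pytest.fixture(scope="session")
def lateral_prior():
    """Tuned skeptical prior for the pre-cohort lateral-hit proportion (80/231)."""
    return tune_sigma(80 / 231, 10.0, seed=11)


@pytest.fixture(scope="session")
def paper_quadrature_bundle():
    """One deterministic full-pipeline run on the bundled fixture (shared)."""
    return run_pipeline(paper_run_config(engine="quadrature", seed=20231122))
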