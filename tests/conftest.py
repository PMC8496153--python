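import pytest

from umg.pipeline import PipelineParams, run_cohort
from umg.synthdata import SyntheticCohort, SyntheticCohortSpec, generate_cohort

#: Scaled-down cohort for fast unit/integration tests.
SMALL_SPEC = SyntheticCohortSpec(
    random_seed=7,
    n_genes=400,
    n_samples=40,
    n_planted_drivers=6,
    n_planted_umgs=8,
    n_neighbors_per_umg=4,
    n_driver_links_per_umg=3,
)
SMALL_PARAMS = PipelineParams(cohort="SYNTH", beta=0.15, rank_threshold=200)


@pytest.fixture(scope="session")
def default_cohort() -> SyntheticCohort:
    """The default study conditions: 2000 genes, 100 samples, fixed seed."""
    return generate_cohort(SyntheticCohortSpec(random_seed=1))


@pytest.fixture(scope="session")
def default_report(default_cohort):
    return run_cohort(default_cohort)


@pytest.fixture(scope="session")
def small_cohort() -> SyntheticCohort:
    return generate_cohort(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_report(small_cohort):
    return run_cohort(small_cohort, params=SMALL_PARAMS)
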