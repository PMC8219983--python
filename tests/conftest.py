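import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from slofe.pipeline import PipelineConfig, run_stages
from slofe.synth import FixtureSpec, make_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def fixture():
    """The default synthetic genome: 10 operons, 5 SRPS, noise sigma 0.1."""
    return make_fixture(FixtureSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def pipeline_result(fixture):
    """Full pipeline run on the default fixture (computed once per session)."""
    return run_stages(
        [fixture.genome],
        fixture.genes,
        fixture.operons,
        PipelineConfig(),
        depths=fixture.depths,
        expression=fixture.depths,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_genome(rng, n, gc=0.37):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
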