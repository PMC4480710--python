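import pytest
from hypothesis import HealthCheck, settings

from mdm2strat import panel_curation as pc
from mdm2strat import synthetic_data as sd

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def default_fixture():
    """The default 260-line screen bundle (seed 1)."""
    return sd.gen_screen_registry(sd.FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def curated_result(default_fixture):
    """Cascade output on the default fixture: (curated registry, audit)."""
    fx = default_fixture
    return pc.apply_exclusion_cascade(
        fx.registry, fx.mutations, fx.genotypes, fx.reference_genotypes
    )
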