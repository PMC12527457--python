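import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tierpoi.models import FilterConfig
from tierpoi.pipeline import analyze_bundle
from tierpoi.synthetic_data import make_table_fixtures


@pytest.fixture(scope="session")
def table_bundle():
    """The combined familial + sporadic published-table fixture cohort."""
    return make_table_fixtures()


@pytest.fixture(scope="session")
def table_analysis(table_bundle):
    """Full pipeline run (screen -> aggregate -> summarize) on the fixture."""
    return analyze_bundle(table_bundle)


@pytest.fixture()
def cfg():
    return FilterConfig()


@pytest.fixture(scope="session")
def entity_of(table_bundle):
    return {
        i.sample_id: (i.kindred_id if i.subcohort == "familial" else i.sample_id)
        for i in table_bundle.pedigree
    }
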