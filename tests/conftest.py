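import pytest
from hypothesis import HealthCheck, settings

from desatsig import resources
from desatsig.synthetic_data import PromoterSpec, gen_promoters

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rcsad1():
    return resources.get_rcsad1()


@pytest.fixture(scope="session")
def pocket_table():
    return resources.load_pocket_table()


@pytest.fixture(scope="session")
def family_records():
    return resources.load_family_records()


@pytest.fixture(scope="session")
def reference_records():
    return resources.load_reference_panel_records()


@pytest.fixture(scope="session")
def results_promoters():
    """Promoter fixture mirroring the published cis-element landscape."""
    records, truth = gen_promoters(PromoterSpec.results_layout(seed=20190531))
    return records, truth
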