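import pytest

from helpers import make_visits, visit


@pytest.fixture
def toy_visits():
    """Five patients exercising the three-clause inclusion rule."""
    return make_visits(
        [
            visit("p1", "h1", icd="F10"),
            visit("p2", "h1", icpc="P76"),
            visit("p3", "h2", service="mh_substance", flag=True),
            visit("p4", "h2", icd="K50"),
            visit("p5", "h3", icd="F81"),
        ]
    )


@pytest.fixture(scope="session")
def small_registry():
    from psnet.synthetic import SyntheticConfig, generate_registry

    return generate_registry(
        SyntheticConfig(n_patients_total=400, n_professionals=100, seed=5)
    )


@pytest.fixture(scope="session")
def small_cohort(small_registry):
    from psnet.cohort import filter_cohort

    visits, _ = filter_cohort(small_registry)
    return visits
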