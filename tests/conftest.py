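import pytest
from hypothesis import HealthCheck, settings

import seedfate as sf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_data() -> sf.FieldDataset:
    """The packaged reference campaign (original design, 7 censored trays)."""
    return sf.study_dataset()


@pytest.fixture(scope="session")
def study_estimates(study_data):
    tables = sf.estimate_transition_tables(study_data)
    dispersal = sf.estimate_dispersal_distribution(study_data.faeces)
    return tables, dispersal, study_data.cover


@pytest.fixture()
def small_tables():
    """Hand-written transition tables covering all three stages."""
    pred = sf.TransitionTable(
        sf.PREDATION_SURVIVAL,
        {
            (sf.OPEN,): [0.4, 0.6],
            (sf.EPHEDRA,): [0.1, 0.2],
            (sf.PISTACIA,): [0.3],
        },
    )
    emer = sf.TransitionTable(
        sf.EMERGENCE,
        {
            (m, t): [0.5, 0.3]
            for m in sf.CORE_MICROHABITATS
            for t in sf.TREATMENTS
        },
    )
    surv = sf.TransitionTable(
        sf.SEEDLING_SURVIVAL,
        {
            (m, t): [0.2]
            for m in sf.CORE_MICROHABITATS
            for t in sf.TREATMENTS
        },
    )
    return {sf.PREDATION_SURVIVAL: pred, sf.EMERGENCE: emer, sf.SEEDLING_SURVIVAL: surv}


@pytest.fixture()
def uniform_dispersal():
    return sf.DispersalDistribution({sf.OPEN: 0.5, sf.EPHEDRA: 0.25, sf.PISTACIA: 0.25})
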