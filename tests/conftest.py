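import numpy as np
import pytest

from diolkin import (
    KineticParams,
    ModelVariant,
    NoiseModel,
    StagedFitConfig,
    SyntheticScenario,
    default_initial_state,
    generate_timecourse,
    builtin_fixtures,
    staged_fit_protocol,
)

G0 = 222.0


@pytest.fixture
def initial_state():
    return default_initial_state(G0)


@pytest.fixture(scope="session")
def fixtures():
    """The three shipped synthetic datasets (fixed seed, default noise)."""
    return builtin_fixtures(seed=0)


@pytest.fixture(scope="session")
def staged_outcome(fixtures):
    """Staged protocol run once on the shipped fixtures (expensive)."""
    return staged_fit_protocol(
        fixtures["mr40"][0], fixtures["dko_phabj"][0], fixtures["dko_fadb"][0]
    )


@pytest.fixture(scope="session")
def staged_outcome_linear(fixtures):
    """Staged protocol on knockout data generated WITHOUT inhibition."""
    noise = NoiseModel()
    lin = KineticParams.for_variant(
        ModelVariant.DKO_PHABJ, {"Ka1": 0.003, "Km2": 0.09, "Ka3": 0.08}
    )
    dko, _ = generate_timecourse(
        SyntheticScenario(variant=ModelVariant.DKO_PHABJ, params=lin, noise=noise),
        seed=11,
    )
    slow = KineticParams.for_variant(
        ModelVariant.DKO_PHABJ, {"Ka1": 0.0017, "Km2": 0.09, "Ka3": 0.08}
    )
    fadb, _ = generate_timecourse(
        SyntheticScenario(variant=ModelVariant.DKO_PHABJ, params=slow, noise=noise),
        seed=12,
    )
    return staged_fit_protocol(fixtures["mr40"][0], dko, fadb, StagedFitConfig())
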