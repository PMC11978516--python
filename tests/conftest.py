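import numpy as np
import pytest

from predforage import (
    LogisticPolicyAgent,
    PolicyParams,
    ScriptedAgent,
    TaskConfig,
    epochize,
    generate_schedule,
    run_session,
)
from predforage.screening import classify_epochs


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def schedule(config):
    return generate_schedule(config, seed=1)


@pytest.fixture(scope="session")
def default_log(schedule, config):
    agent = LogisticPolicyAgent(PolicyParams.default())
    return run_session(schedule, agent, seed=7, config=config, participant_id="pfix")


@pytest.fixture(scope="session")
def records(default_log, config):
    return epochize(default_log, config)


@pytest.fixture(scope="session")
def availability(records):
    return classify_epochs(records)


@pytest.fixture(scope="session")
def forager_log(schedule, config):
    return run_session(schedule, ScriptedAgent("always_forage"), seed=3, config=config)


@pytest.fixture(scope="session")
def hider_log(schedule, config):
    return run_session(schedule, ScriptedAgent("check_then_hide"), seed=3, config=config)


@pytest.fixture(scope="session")
def checker_log(schedule, config):
    return run_session(schedule, ScriptedAgent("always_check"), seed=3, config=config)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results never depend on the
    # order in which tests consume random draws
    return np.random.default_rng(20240917)
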