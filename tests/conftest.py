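import pytest

from prscreen import baseline_parameters
from prscreen.strategies import build_current_strategy, build_tailored_strategy


@pytest.fixture(scope="session")
def params():
    return baseline_parameters()


@pytest.fixture(scope="session")
def current(params):
    return build_current_strategy(params.config)


@pytest.fixture(scope="session")
def tailored(params):
    return build_tailored_strategy(params.strat, params.config)
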