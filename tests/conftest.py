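import numpy as np
import pytest

from riskchoice import Gamble, ModelSpec
from riskchoice.synthetic_agent import AgentSpec


@pytest.fixture
def deg():
    """Degenerate-gamble factory."""
    return Gamble.degenerate


@pytest.fixture
def eu_power_agent():
    """The reference risk-averse expected-utility agent (a=0.8, tau=0.05)."""
    return AgentSpec(model=ModelSpec("EU_power", {"a": 0.8, "tau": 0.05}),
                     seed=7)


@pytest.fixture
def ev_agent():
    """Risk-neutral agent choosing by normalized expected value."""
    return AgentSpec(model=ModelSpec("EV", {"tau": 0.05}), seed=11)


@pytest.fixture
def levels11():
    """The study's 11-point mixture-probability grid (0 to 1, step 0.1)."""
    return np.round(np.linspace(0.0, 1.0, 11), 6)
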