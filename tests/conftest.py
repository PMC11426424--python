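import numpy as np
import pytest

from refinebandit.agents import Agent, RepertoireEntry
from refinebandit.config import SimulationConfig
from refinebandit.environment import BanditEnvironment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    """A small, fast baseline configuration."""
    return SimulationConfig(extension="none", p_c=0.0, p_copyFail=0.0, n_observe=1)


@pytest.fixture
def cumulative_cfg():
    return SimulationConfig(extension="cumulative", p_c=0.0, p_copyFail=0.0, r_max=100)


def make_env(payoffs, change_prob=0.0):
    """Environment from an explicit payoff table (1-D => single deme)."""
    table = np.atleast_2d(np.asarray(payoffs, dtype=np.int64))
    return BanditEnvironment(payoffs=table, change_prob=change_prob)


def make_agent(agent_id=0, entry_id="test", deme=0, repertoire=None, levels=None):
    """Agent with a pre-seeded repertoire {behavior: recorded_payoff}."""
    agent = Agent(agent_id, entry_id, deme)
    for b, payoff in (repertoire or {}).items():
        level = (levels or {}).get(b, 0)
        agent.repertoire[b] = RepertoireEntry(b, float(payoff), level)
    return agent
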