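import numpy as np
import pytest

from nudgegame import (
    GameConfig,
    PlayerRef,
    make_players,
    make_policies,
    run_game,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def study1_config():
    """A 30-round, 30-token game with one agent per group (3 humans + 1
    agent in each group)."""
    return GameConfig(
        game_id="g1",
        condition="1:1",
        rounds=30,
        starting_tokens=30,
        agents_per_group=(1, 1),
        wave_length=6,
        seed=42,
    )


@pytest.fixture
def study2_config():
    """A 15-round, 40-token game with two agents in group 1 only."""
    return GameConfig(
        game_id="g2",
        condition="2:0",
        rounds=15,
        starting_tokens=40,
        agents_per_group=(2, 0),
        wave_length=5,
        seed=43,
    )


@pytest.fixture
def null_config():
    """An agent-free 15-round game."""
    return GameConfig(
        game_id="g0",
        condition="null",
        rounds=15,
        starting_tokens=40,
        agents_per_group=(0, 0),
        wave_length=5,
        seed=44,
    )


@pytest.fixture
def study1_log(study1_config):
    return run_game(study1_config, make_policies(study1_config))


@pytest.fixture
def null_log(null_config):
    return run_game(null_config, make_policies(null_config))


def two_group_roster():
    """A fixed 8-player roster: 3 humans + 1 agent per group."""
    cfg = GameConfig(
        game_id="toy",
        condition="1:1",
        rounds=6,
        starting_tokens=6,
        agents_per_group=(1, 1),
        wave_length=6,
        seed=0,
    )
    return cfg, make_players(cfg)


@pytest.fixture
def toy_roster():
    return two_group_roster()


def human(pid: str, group: int) -> PlayerRef:
    return PlayerRef(id=pid, group=group, kind="human")
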