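"""Deterministic, seeded execution of the round-based exchange game.

Play is simultaneous within a round: all eight allocation decisions are
computed from the public state at the end of the previous round, then
applied together. This mirrors a platform that reveals exchanges only at
the end of each round, so no intra-round ordering can leak information
between players.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .types import AllocationEvent, GameConfig, GameLog, PlayerRef, make_players


class Policy(Protocol):
    """An allocation policy: given the public state, pick a recipient."""

    def choose(
        self, state: "GameState", player: PlayerRef, rng: np.random.Generator
    ) -> PlayerRef: ...


@dataclass
class _ReciprocityStats:
    """Incremental per-player reciprocation bookkeeping (window = 1)."""

    opportunities: int = 0
    taken: int = 0


@dataclass
class GameState:
    """Mutable state of a running game.

    ``round`` counts completed rounds; decisions for round ``round + 1``
    see the history of rounds ``1..round`` only. The engine maintains
    incremental per-player tallies (non-self ingroup/outgroup giving and
    window-1 reciprocation counts) so policies and feature extraction do
    not need to rescan the event list every round.
    """

    config: GameConfig
    players: list[PlayerRef]
    round: int = 0
    balances: dict[str, int] = field(default_factory=dict)
    history: list[AllocationEvent] = field(default_factory=list)
    # derived tallies, updated by play_round
    given_ingroup: dict[str, int] = field(default_factory=dict)
    given_outgroup: dict[str, int] = field(default_factory=dict)
    reciprocity: dict[str, _ReciprocityStats] = field(default_factory=dict)

    def players_by_id(self) -> dict[str, PlayerRef]:
        return {p.id: p for p in self.players}

    def outgroup(self, player: PlayerRef) -> list[PlayerRef]:
        return [p for p in self.players if p.group != player.group]

    def ingroup_others(self, player: PlayerRef) -> list[PlayerRef]:
        return [
            p for p in self.players if p.group == player.group and p.id != player.id
        ]

    def recent_events(self, window: int) -> list[AllocationEvent]:
        """Events from the last ``window`` completed rounds."""
        cutoff = self.round - window
        return [e for e in self.history if e.round > cutoff]


def init_game(
    config: GameConfig, policy_assignment: dict[str, Policy]
) -> GameState:
    """Set up a game: full balances, empty history, round 0.

    ``policy_assignment`` must cover exactly the roster implied by the
    config (same ids, agent placement per ``agents_per_group``).
    """
    players = make_players(config)
    expected = {p.id for p in players}
    supplied = set(policy_assignment)
    if supplied != expected:
        raise ValueError(
            f"policy assignment does not match roster: missing "
            f"{sorted(expected - supplied)}, unexpected {sorted(supplied - expected)}"
        )
    return GameState(
        config=config,
        players=players,
        round=0,
        balances={p.id: config.starting_tokens for p in players},
        given_ingroup={p.id: 0 for p in players},
        given_outgroup={p.id: 0 for p in players},
        reciprocity={p.id: _ReciprocityStats() for p in players},
    )


def play_round(
    state: GameState,
    policy_assignment: dict[str, Policy],
    rng: np.random.Generator,
) -> GameState:
    """Play one round in place: eight simultaneous decisions, then apply.

    Decisions are computed in fixed player-id order from the state as it
    stood at the end of the previous round, so the outcome is a pure
    function of (state, seed). Mutates and returns ``state``.
    """
    if state.round >= state.config.rounds:
        raise RuntimeError(
            f"game is over: {state.round} of {state.config.rounds} rounds played"
        )
    this_round = state.round + 1

    # who gave to whom last round, for the window-1 reciprocation tally
    last_round_givers: dict[str, set[str]] = {p.id: set() for p in state.players}
    for e in state.recent_events(1):
        if e.allocator.id != e.recipient.id:
            last_round_givers[e.recipient.id].add(e.allocator.id)

    decisions: list[tuple[PlayerRef, PlayerRef]] = []
    for player in sorted(state.players, key=lambda p: p.id):
        recipient = policy_assignment[player.id].choose(state, player, rng)
        decisions.append((player, recipient))

    for player, recipient in decisions:
        state.history.append(
            AllocationEvent(
                game_id=state.config.game_id,
                round=this_round,
                allocator=player,
                recipient=recipient,
            )
        )
        state.balances[player.id] -= 1
        state.balances[recipient.id] += 1
        if recipient.id != player.id:
            if recipient.group == player.group:
                state.given_ingroup[player.id] += 1
            else:
                state.given_outgroup[player.id] += 1
        givers = last_round_givers[player.id]
        if givers:
            stats = state.reciprocity[player.id]
            stats.opportunities += 1
            if recipient.id in givers:
                stats.taken += 1

    state.round = this_round
    return state


def run_game(
    config: GameConfig,
    policy_assignment: dict[str, Policy],
    seed: int | None = None,
    *,
    with_ratings: bool = True,
    trial_rounds: int = 0,
) -> GameLog:
    """Run a full game and return its log; bit-reproducible from the seed.

    ``trial_rounds`` optionally plays an unscored warm-up game of that
    many rounds first (its events are discarded entirely and balances
    reset), emulating a practice phase; default off, and no metric ever
    sees warm-up events. Ratings are produced by the synthetic rating
    model unless ``with_ratings`` is false.
    """
    from .participants import generate_ratings  # deferred: avoids import cycle

    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    if trial_rounds > 0:
        trial_cfg = GameConfig(
            game_id=config.game_id + "_trial",
            condition=config.condition,
            rounds=trial_rounds,
            starting_tokens=max(config.starting_tokens, trial_rounds),
            agents_per_group=config.agents_per_group,
            wave_length=trial_rounds,
            seed=seed,
            group_size=config.group_size,
        )
        trial_state = init_game(trial_cfg, policy_assignment)
        for _ in range(trial_rounds):
            play_round(trial_state, policy_assignment, rng)

    # reset any stateful (e.g. model-caching) policies before the scored game
    for policy in {id(p): p for p in policy_assignment.values()}.values():
        reset = getattr(policy, "reset", None)
        if callable(reset):
            reset()

    state = init_game(config, policy_assignment)
    for _ in range(config.rounds):
        play_round(state, policy_assignment, rng)

    ratings = generate_ratings(state.players, state.history, rng) if with_ratings else []
    return GameLog(
        config=config,
        players=state.players,
        events=list(state.history),
        ratings=ratings,
        final_balances=dict(state.balances),
    )
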