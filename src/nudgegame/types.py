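"""Core domain types for the token-exchange game.

A game is played by eight players split into two groups of four. Each
round every player allocates exactly one token to some player (possibly
themself). Players are either humans (synthetic policy-driven
participants) or embedded nudge agents. The types here carry the full
round-by-round record of a game plus the post-game 1-5 ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

PlayerKind = Literal["human", "agent"]
RatingType = Literal["fairness", "humanness"]

#: Number of players in every valid game (two groups of four).
N_PLAYERS = 8


@dataclass(frozen=True)
class PlayerRef:
    """A player identity: unique id, group membership (1 or 2), and kind."""

    id: str
    group: int
    kind: PlayerKind

    def __post_init__(self) -> None:
        if self.group not in (1, 2):
            raise ValueError(f"group must be 1 or 2, got {self.group}")
        if self.kind not in ("human", "agent"):
            raise ValueError(f"kind must be 'human' or 'agent', got {self.kind!r}")


@dataclass(frozen=True)
class GameConfig:
    """Static design of a single game.

    Parameters
    ----------
    game_id:
        Unique label for the game.
    condition:
        Condition label, e.g. ``"2:0"`` (two agents in group 1, none in
        group 2) or ``"null"``.
    rounds:
        Number of scored rounds (30 in the long design, 15 in the short).
    starting_tokens:
        Tokens each player holds at round 0; must be >= rounds so that a
        player who never receives anything can still allocate every round.
    agents_per_group:
        Pair ``(a1, a2)`` of agent counts in groups 1 and 2.
    wave_length:
        Rounds per wave for the ingroup-favoritism time series; must
        divide ``rounds`` (6-round waves for 30-round games, 5-round
        waves for 15-round games).
    seed:
        Seed for the game's own random stream.
    group_size:
        Players per group (4 in every design considered here).
    """

    game_id: str
    condition: str
    rounds: int
    starting_tokens: int
    agents_per_group: tuple[int, int]
    wave_length: int
    seed: int
    group_size: int = 4

    def __post_init__(self) -> None:
        a1, a2 = self.agents_per_group
        if not (0 <= a1 <= self.group_size and 0 <= a2 <= self.group_size):
            raise ValueError(
                f"agents_per_group {self.agents_per_group} outside "
                f"[0, {self.group_size}]"
            )
        if self.rounds % self.wave_length != 0:
            raise ValueError(
                f"rounds ({self.rounds}) not divisible by wave_length "
                f"({self.wave_length})"
            )
        if self.starting_tokens < self.rounds:
            raise ValueError(
                "starting_tokens must be >= rounds to guarantee non-negative "
                f"balances ({self.starting_tokens} < {self.rounds})"
            )
        # normalize tuple-ness (configs loaded from JSON carry lists)
        object.__setattr__(self, "agents_per_group", (int(a1), int(a2)))

    @property
    def n_players(self) -> int:
        return 2 * self.group_size

    @property
    def n_waves(self) -> int:
        return self.rounds // self.wave_length


@dataclass(frozen=True)
class AllocationEvent:
    """One token transfer: ``allocator`` gave one token to ``recipient``.

    Rounds are 1-based. Self-giving (allocator == recipient) is a legal
    move for humans and is recorded like any other event.
    """

    game_id: str
    round: int
    allocator: PlayerRef
    recipient: PlayerRef


@dataclass(frozen=True)
class RatingRecord:
    """A post-game 1-5 judgement by a human rater of another player."""

    rater: PlayerRef
    target: PlayerRef
    rating_type: RatingType
    value: int


@dataclass
class GameLog:
    """The complete record of one game: design, roster, events, ratings."""

    config: GameConfig
    players: list[PlayerRef]
    events: list[AllocationEvent]
    ratings: list[RatingRecord] = field(default_factory=list)
    final_balances: dict[str, int] = field(default_factory=dict)

    def humans(self) -> list[PlayerRef]:
        return [p for p in self.players if p.kind == "human"]

    def agents(self) -> list[PlayerRef]:
        return [p for p in self.players if p.kind == "agent"]

    def group_members(self, group: int) -> list[PlayerRef]:
        return [p for p in self.players if p.group == group]


def make_players(config: GameConfig) -> list[PlayerRef]:
    """Build the 8-player roster implied by a config.

    Within each group, agents come first (``G{g}A{k}``) followed by
    humans (``G{g}H{k}``); the ordering is deterministic so that a game
    is fully reproducible from its config.
    """
    players: list[PlayerRef] = []
    for g in (1, 2):
        n_agents = config.agents_per_group[g - 1]
        for k in range(1, n_agents + 1):
            players.append(PlayerRef(id=f"G{g}A{k}", group=g, kind="agent"))
        for k in range(1, config.group_size - n_agents + 1):
            players.append(PlayerRef(id=f"G{g}H{k}", group=g, kind="human"))
    return players


def validate_log(log: GameLog) -> list[str]:
    """Check every GameLog invariant; return a description per violation.

    An empty list means the log is conformant. Violations are returned,
    never raised, so callers can decide severity.
    """
    v: list[str] = []
    cfg = log.config

    ids = [p.id for p in log.players]
    if len(set(ids)) != len(ids):
        v.append("duplicate player ids")
    if len(log.players) != cfg.n_players:
        v.append(f"expected {cfg.n_players} players, found {len(log.players)}")
    for g in (1, 2):
        n = sum(1 for p in log.players if p.group == g)
        if n != cfg.group_size:
            v.append(f"group {g} has {n} players, expected {cfg.group_size}")
    for g in (1, 2):
        n_agents = sum(1 for p in log.players if p.group == g and p.kind == "agent")
        if n_agents != cfg.agents_per_group[g - 1]:
            v.append(
                f"group {g} has {n_agents} agents, config says "
                f"{cfg.agents_per_group[g - 1]}"
            )

    id_set = set(ids)
    expected_events = cfg.n_players * cfg.rounds
    if len(log.events) != expected_events:
        v.append(f"expected {expected_events} events, found {len(log.events)}")
    seen: set[tuple[str, int]] = set()
    for i, e in enumerate(log.events):
        if e.game_id != cfg.game_id:
            v.append(f"event row {i}: game_id {e.game_id!r} != {cfg.game_id!r}")
            break
    for i, e in enumerate(log.events):
        if e.allocator.id not in id_set or e.recipient.id not in id_set:
            v.append(f"event row {i}: player not in roster")
            break
    for i, e in enumerate(log.events):
        key = (e.allocator.id, e.round)
        if key in seen:
            v.append(f"event row {i}: duplicate allocation by {key[0]} in round {key[1]}")
            break
        seen.add(key)
    if not all(1 <= e.round <= cfg.rounds for e in log.events):
        v.append("event round outside [1, rounds]")

    if log.final_balances:
        total = sum(log.final_balances.values())
        expected_total = cfg.n_players * cfg.starting_tokens
        if total != expected_total:
            v.append(
                f"token conservation violated: balances sum to {total}, "
                f"expected {expected_total}"
            )
        negative = [pid for pid, b in log.final_balances.items() if b < 0]
        if negative:
            v.append(f"negative final balance for {negative}")

    for i, r in enumerate(log.ratings):
        if not 1 <= r.value <= 5:
            v.append(f"rating row {i}: value {r.value} outside [1, 5]")
            break
    for i, r in enumerate(log.ratings):
        if r.rater.kind != "human":
            v.append(f"rating row {i}: rater {r.rater.id} is not human")
            break
    for i, r in enumerate(log.ratings):
        if r.rater.id == r.target.id:
            v.append(f"rating row {i}: self-rating by {r.rater.id}")
            break

    return v
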