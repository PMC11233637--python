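"""Dependent variables of the exchange game.

* **Ingroup favoritism** per wave: a human player's ingroup allocations
  over their ingroup-plus-outgroup allocations within a contiguous block
  of rounds (a wave). Self-giving is a self-favoring strategy, not a
  group-favoring one, so it is excluded from both numerator and
  denominator; agent-produced events are excluded entirely. A wave with
  no non-self allocations has no defined ratio and propagates as
  missing.

* **Normalized allocation** n_x / N_x by target category: allocations
  from a group's humans to targets of a category (ingroup human,
  ingroup agent, outgroup human, outgroup agent), normalized by the
  number of eligible human allocators per target — for a group of three
  humans and one agent, N = 3 for the ingroup agent, outgroup humans and
  outgroup agents, and N = 2 for an ingroup human, because
  self-allocations are removed. Ratios are additionally averaged per
  round and per target so they are comparable across designs.

* **Withdrawal contrast**: normalized allocation to ingroup humans minus
  ingroup agents; positive values mean humans withheld cooperation from
  their ingroup agents.

* **Rating summaries**: mean/SD/n of 1-5 fairness and humanness ratings
  in the four cells (ingroup/outgroup target) x (human/agent target).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AllocationEvent, GameLog, PlayerRef

CATEGORIES = ("ingroup_human", "ingroup_agent", "outgroup_human", "outgroup_agent")


class AbsentCategoryError(ValueError):
    """The requested target category does not exist in the group layout."""


@dataclass
class IFSeries:
    """Per-wave ingroup favoritism of one human player.

    ``values`` holds (wave index, ratio) pairs; the ratio is ``None``
    where the wave had no non-self allocations.
    """

    player: PlayerRef
    values: list[tuple[int, float | None]]


@dataclass
class NormalizedAllocation:
    """Normalized allocation for one (game, group, category) cell.

    ``n`` is the raw allocation count from the group's humans to the
    category's targets (self-allocations removed), ``N`` the eligible
    human allocator count per target, and ``ratio`` the per-round,
    per-target normalized rate n / (N x targets x rounds).
    """

    game_id: str
    group: int
    category: str
    n: int
    N: int
    n_targets: int
    ratio: float


def ingroup_favoritism(
    events: list[AllocationEvent], wave_start: int, wave_end: int
) -> float | None:
    """Ingroup favoritism of one player over rounds [wave_start, wave_end].

    ``events`` must all belong to a single allocator. Returns
    IA / (IA + OA) with self-giving excluded from both counts, or
    ``None`` when the player made no non-self allocation in the wave.
    """
    if wave_start > wave_end:
        raise ValueError("wave_start must be <= wave_end")
    allocators = {e.allocator.id for e in events}
    if len(allocators) > 1:
        raise ValueError(f"events from multiple players: {sorted(allocators)}")
    ia = oa = 0
    for e in events:
        if not wave_start <= e.round <= wave_end:
            continue
        if e.recipient.id == e.allocator.id:
            continue
        if e.recipient.group == e.allocator.group:
            ia += 1
        else:
            oa += 1
    if ia + oa == 0:
        return None
    return ia / (ia + oa)


def if_series(log: GameLog, wave_length: int | None = None) -> list[IFSeries]:
    """Per-wave ingroup favoritism for every human in the log.

    30-round games with 6-round waves yield 5 values per human; 15-round
    games with 5-round waves yield 3. Agents are excluded.
    """
    wave_length = wave_length or log.config.wave_length
    if log.config.rounds % wave_length != 0:
        raise ValueError(
            f"rounds ({log.config.rounds}) not divisible by wave_length ({wave_length})"
        )
    n_waves = log.config.rounds // wave_length
    by_player: dict[str, list[AllocationEvent]] = {}
    for e in log.events:
        by_player.setdefault(e.allocator.id, []).append(e)

    out: list[IFSeries] = []
    for p in log.humans():
        events = by_player.get(p.id, [])
        values: list[tuple[int, float | None]] = []
        for w in range(1, n_waves + 1):
            start = (w - 1) * wave_length + 1
            end = w * wave_length
            values.append((w, ingroup_favoritism(events, start, end)))
        out.append(IFSeries(player=p, values=values))
    return out


def if_table(log: GameLog, wave_length: int | None = None) -> pd.DataFrame:
    """Tidy one-row-per-(player, wave) ingroup-favoritism table."""
    rows = []
    for series in if_series(log, wave_length):
        for wave, value in series.values:
            rows.append(
                {
                    "game_id": log.config.game_id,
                    "condition": log.config.condition,
                    "group": series.player.group,
                    "player_id": series.player.id,
                    "wave": wave,
                    "if_value": np.nan if value is None else value,
                }
            )
    return pd.DataFrame(
        rows, columns=["game_id", "condition", "group", "player_id", "wave", "if_value"]
    )


def _category_targets(log: GameLog, group: int, category: str) -> list[PlayerRef]:
    rel, kind = category.split("_")
    target_group = group if rel == "ingroup" else 3 - group
    return [p for p in log.players if p.group == target_group and p.kind == kind]


def normalized_allocation(
    log: GameLog, group: int, category: str
) -> NormalizedAllocation:
    """Normalized allocation from ``group``'s humans to one target category.

    Raises :class:`AbsentCategoryError` when the category has no targets
    in the game's composition (e.g. ingroup agents in an agentless
    group). N is the per-target count of eligible human allocators in
    ``group`` (group humans, minus one for a human target in the same
    group, since self-allocation is removed).
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    allocators = [p for p in log.players if p.group == group and p.kind == "human"]
    if not allocators:
        raise AbsentCategoryError(f"group {group} has no human allocators")
    targets = _category_targets(log, group, category)
    if not targets:
        raise AbsentCategoryError(
            f"category {category} absent from group {group}'s perspective"
        )

    rel, kind = category.split("_")
    N = len(allocators) - 1 if (rel == "ingroup" and kind == "human") else len(allocators)
    if N < 1:
        raise AbsentCategoryError(
            f"no eligible allocators for category {category} in group {group}"
        )

    allocator_ids = {p.id for p in allocators}
    target_ids = {p.id for p in targets}
    n = sum(
        1
        for e in log.events
        if e.allocator.id in allocator_ids
        and e.recipient.id in target_ids
        and e.recipient.id != e.allocator.id
    )
    ratio = n / (N * len(targets) * log.config.rounds)
    return NormalizedAllocation(
        game_id=log.config.game_id,
        group=group,
        category=category,
        n=n,
        N=N,
        n_targets=len(targets),
        ratio=ratio,
    )


def allocation_table(log: GameLog) -> pd.DataFrame:
    """Normalized allocations for every present (group, category) cell."""
    rows = []
    for group in (1, 2):
        for category in CATEGORIES:
            try:
                na = normalized_allocation(log, group, category)
            except AbsentCategoryError:
                continue
            rows.append(
                {
                    "game_id": na.game_id,
                    "condition": log.config.condition,
                    "group": na.group,
                    "category": na.category,
                    "n": na.n,
                    "N": na.N,
                    "n_targets": na.n_targets,
                    "ratio": na.ratio,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["game_id", "condition", "group", "category", "n", "N", "n_targets", "ratio"],
    )


def withdrawal_contrast(log: GameLog, group: int | None = None) -> dict[int, float]:
    """Ingroup-human minus ingroup-agent normalized allocation per group.

    Positive values mean the group's humans gave relatively less to
    their ingroup agents than to each other — withdrawal of cooperation.
    Only groups with at least one agent and two humans are measurable;
    raises :class:`AbsentCategoryError` if no group (or the requested
    group) qualifies.
    """
    groups = (group,) if group is not None else (1, 2)
    out: dict[int, float] = {}
    for g in groups:
        humans = [p for p in log.players if p.group == g and p.kind == "human"]
        agents = [p for p in log.players if p.group == g and p.kind == "agent"]
        if len(agents) < 1 or len(humans) < 2:
            continue
        human_ratio = normalized_allocation(log, g, "ingroup_human").ratio
        agent_ratio = normalized_allocation(log, g, "ingroup_agent").ratio
        out[g] = human_ratio - agent_ratio
    if not out:
        raise AbsentCategoryError(
            "no group with both an ingroup agent and >= 2 humans"
        )
    return out


def rating_summary(ratings: list) -> pd.DataFrame:
    """Mean/SD/n of ratings per (rating_type, target relation, target kind).

    The relation is judged from the rater: ingroup if rater and target
    share a group. SD is the sample standard deviation (0.0 for a single
    rating). Raises on empty input.
    """
    if not ratings:
        raise ValueError("empty ratings collection")
    rows = [
        {
            "rating_type": r.rating_type,
            "relation": "ingroup" if r.rater.group == r.target.group else "outgroup",
            "target_kind": r.target.kind,
            "value": r.value,
        }
        for r in ratings
    ]
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["rating_type", "relation", "target_kind"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return summary
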