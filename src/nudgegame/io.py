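"""Reading and writing game logs.

A game log on disk is a directory with three files:

* ``events.csv`` — one row per allocation (game_id, condition, round,
  allocator_id, allocator_group, allocator_kind, recipient_id,
  recipient_group, recipient_kind);
* ``ratings.csv`` — one row per post-game rating;
* ``config.json`` — the game config, the roster and the final balances.

CSV is RFC 4180, UTF-8, with a header row, so that externally collected
event data can be mapped in by renaming columns. Configs may also be
supplied in YAML.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .types import (
    AllocationEvent,
    GameConfig,
    GameLog,
    PlayerRef,
    RatingRecord,
    validate_log,
)

EVENT_COLUMNS = [
    "game_id",
    "condition",
    "round",
    "allocator_id",
    "allocator_group",
    "allocator_kind",
    "recipient_id",
    "recipient_group",
    "recipient_kind",
]

RATING_COLUMNS = [
    "game_id",
    "rater_id",
    "rater_group",
    "rater_kind",
    "target_id",
    "target_group",
    "target_kind",
    "rating_type",
    "value",
]


class SchemaError(ValueError):
    """A log file does not conform to the on-disk schema."""


def events_to_frame(log: GameLog) -> pd.DataFrame:
    rows = [
        {
            "game_id": e.game_id,
            "condition": log.config.condition,
            "round": e.round,
            "allocator_id": e.allocator.id,
            "allocator_group": e.allocator.group,
            "allocator_kind": e.allocator.kind,
            "recipient_id": e.recipient.id,
            "recipient_group": e.recipient.group,
            "recipient_kind": e.recipient.kind,
        }
        for e in log.events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def ratings_to_frame(log: GameLog) -> pd.DataFrame:
    rows = [
        {
            "game_id": log.config.game_id,
            "rater_id": r.rater.id,
            "rater_group": r.rater.group,
            "rater_kind": r.rater.kind,
            "target_id": r.target.id,
            "target_group": r.target.group,
            "target_kind": r.target.kind,
            "rating_type": r.rating_type,
            "value": r.value,
        }
        for r in log.ratings
    ]
    return pd.DataFrame(rows, columns=RATING_COLUMNS)


def write_game_log(log: GameLog, destination: str | Path) -> None:
    """Write a validated game log to ``destination`` (a directory).

    Raises ``SchemaError`` naming the first violation if the log breaks
    any invariant; a round-trip through :func:`read_game_log` returns a
    structurally identical log.
    """
    violations = validate_log(log)
    if violations:
        raise SchemaError(f"refusing to write invalid log: {violations[0]}")

    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    events_to_frame(log).to_csv(dest / "events.csv", index=False)
    ratings_to_frame(log).to_csv(dest / "ratings.csv", index=False)
    sidecar = {
        "config": {
            "game_id": log.config.game_id,
            "condition": log.config.condition,
            "rounds": log.config.rounds,
            "starting_tokens": log.config.starting_tokens,
            "agents_per_group": list(log.config.agents_per_group),
            "wave_length": log.config.wave_length,
            "seed": log.config.seed,
            "group_size": log.config.group_size,
        },
        "players": [
            {"id": p.id, "group": p.group, "kind": p.kind} for p in log.players
        ],
        "final_balances": log.final_balances,
    }
    (dest / "config.json").write_text(json.dumps(sidecar, indent=1))


def load_config(source: str | Path) -> GameConfig:
    """Load a GameConfig from a JSON or YAML file.

    Accepts either a bare config mapping or a sidecar with a ``config``
    key; keys mirror the GameConfig fields.
    """
    path = Path(source)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if "config" in data:
        data = data["config"]
    data = dict(data)
    data["agents_per_group"] = tuple(data["agents_per_group"])
    return GameConfig(**data)


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file missing mandatory column(s): {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{what} file has unknown column(s) {extra}; ignored")


def read_game_log(source: str | Path) -> GameLog:
    """Read a game-log directory written by :func:`write_game_log`.

    Returns a validated :class:`GameLog`. Unknown extra columns are
    ignored with a warning; schema breaches (missing column, group
    outside {1, 2}, rating outside 1..5, empty events) raise
    ``SchemaError`` naming the offending row.
    """
    src = Path(source)
    sidecar = json.loads((src / "config.json").read_text())
    cfg_data = dict(sidecar["config"])
    cfg_data["agents_per_group"] = tuple(cfg_data["agents_per_group"])
    config = GameConfig(**cfg_data)
    players = [PlayerRef(**p) for p in sidecar["players"]]
    by_id = {p.id: p for p in players}

    events_df = pd.read_csv(src / "events.csv")
    if events_df.empty:
        raise SchemaError("no events")
    _require_columns(events_df, EVENT_COLUMNS, "events")
    events: list[AllocationEvent] = []
    for i, row in enumerate(events_df.itertuples(index=False)):
        for grp in (row.allocator_group, row.recipient_group):
            if grp not in (1, 2):
                raise SchemaError(f"events row {i}: group {grp} outside {{1, 2}}")
        try:
            allocator = by_id[row.allocator_id]
            recipient = by_id[row.recipient_id]
        except KeyError as exc:
            raise SchemaError(f"events row {i}: unknown player {exc}") from None
        events.append(
            AllocationEvent(
                game_id=row.game_id,
                round=int(row.round),
                allocator=allocator,
                recipient=recipient,
            )
        )

    ratings: list[RatingRecord] = []
    ratings_path = src / "ratings.csv"
    if ratings_path.exists():
        ratings_df = pd.read_csv(ratings_path)
        if not ratings_df.empty:
            _require_columns(ratings_df, RATING_COLUMNS, "ratings")
            for i, row in enumerate(ratings_df.itertuples(index=False)):
                if not 1 <= row.value <= 5:
                    raise SchemaError(
                        f"ratings row {i}: value {row.value} outside [1, 5]"
                    )
                ratings.append(
                    RatingRecord(
                        rater=by_id[row.rater_id],
                        target=by_id[row.target_id],
                        rating_type=row.rating_type,
                        value=int(row.value),
                    )
                )

    log = GameLog(
        config=config,
        players=players,
        events=events,
        ratings=ratings,
        final_balances={k: int(v) for k, v in sidecar["final_balances"].items()},
    )
    violations = validate_log(log)
    if violations:
        raise SchemaError(f"log read from {src} is invalid: {violations[0]}")
    return log
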