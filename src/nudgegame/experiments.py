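"""Study designs, the seeded batch runner, and resampling inference.

Two canned designs mirror the studies' condition layouts:

* the long design — five conditions (1:0, 2:0, 1:1, 2:1, 2:2) of agent
  placement, 10 replicated games each, 30 rounds of 6-round waves,
  30 starting tokens;
* the short design — three conditions (null, 2:0, 2:2), 20 replicated
  games each, 15 rounds of 5-round waves, 40 starting tokens.

Per-game seeds are derived from a master seed through a splittable
scheme (one spawn key per game index), so extending a design never
perturbs the seeds of earlier games. Inference over replicated games is
resampling-based: percentile bootstrap confidence intervals and paired
sign-flip permutation tests at the game level (the game is the
replication unit).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as game_io
from .agents import AdaptiveAgentConfig, AdaptiveAgentPolicy, NonadaptiveAgentPolicy
from .engine import Policy, run_game
from .metrics import allocation_table, if_table, rating_summary
from .participants import HumanPolicy, PolicyParams
from .types import GameConfig, GameLog, make_players

STUDY1_CONDITIONS: list[tuple[str, tuple[int, int]]] = [
    ("1:0", (1, 0)),
    ("2:0", (2, 0)),
    ("1:1", (1, 1)),
    ("2:1", (2, 1)),
    ("2:2", (2, 2)),
]

STUDY2_CONDITIONS: list[tuple[str, tuple[int, int]]] = [
    ("null", (0, 0)),
    ("2:0", (2, 0)),
    ("2:2", (2, 2)),
]


@dataclass
class StudyDesign:
    """A full experimental design: one GameConfig per game."""

    study: str
    configs: list[GameConfig]
    replications: int

    @property
    def n_games(self) -> int:
        return len(self.configs)

    def total_agents(self) -> int:
        return sum(sum(c.agents_per_group) for c in self.configs)

    def total_humans(self) -> int:
        return sum(c.n_players - sum(c.agents_per_group) for c in self.configs)


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-game seed from a master seed; adding games never
    changes earlier seeds."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % np.uint32(2**31))


def _build_design(
    study: str,
    conditions: list[tuple[str, tuple[int, int]]],
    replications: int,
    rounds: int,
    starting_tokens: int,
    wave_length: int,
    seed: int,
) -> StudyDesign:
    configs = []
    index = 0
    for condition, agents in conditions:
        for rep in range(1, replications + 1):
            configs.append(
                GameConfig(
                    game_id=f"{study}_{condition.replace(':', '')}_{rep:02d}",
                    condition=condition,
                    rounds=rounds,
                    starting_tokens=starting_tokens,
                    agents_per_group=agents,
                    wave_length=wave_length,
                    seed=derive_seed(seed, index),
                )
            )
            index += 1
    return StudyDesign(study=study, configs=configs, replications=replications)


def build_study1_design(seed: int = 0, replications: int = 10) -> StudyDesign:
    """The five-condition nonadaptive-agent design: 50 games of 30 rounds
    (6-round waves), 30 starting tokens; 280 humans and 120 agents at
    the default replication count."""
    return _build_design("study1", STUDY1_CONDITIONS, replications, 30, 30, 6, seed)


def build_study2_design(seed: int = 0, replications: int = 20) -> StudyDesign:
    """The three-condition adaptive-agent design: 60 games of 15 rounds
    (5-round waves), 40 starting tokens; 360 humans and 120 agents at
    the default replication count."""
    return _build_design("study2", STUDY2_CONDITIONS, replications, 15, 40, 5, seed)


def make_policies(
    config: GameConfig,
    params: PolicyParams | None = None,
    agent_kind: str = "nonadaptive",
    agent_cfg: AdaptiveAgentConfig | None = None,
) -> dict[str, Policy]:
    """Standard policy assignment: one shared HumanPolicy, nonadaptive
    agents, or per-group shared adaptive agents (agents of a group see
    the same public state, so they share one fitted model)."""
    players = make_players(config)
    human = HumanPolicy(params)
    assignment: dict[str, Policy] = {}
    adaptive_by_group: dict[int, AdaptiveAgentPolicy] = {}
    for p in players:
        if p.kind == "human":
            assignment[p.id] = human
        elif agent_kind == "nonadaptive":
            assignment[p.id] = NonadaptiveAgentPolicy()
        elif agent_kind == "adaptive":
            if p.group not in adaptive_by_group:
                adaptive_by_group[p.group] = AdaptiveAgentPolicy(
                    agent_cfg, group=p.group, seed=config.seed
                )
            assignment[p.id] = adaptive_by_group[p.group]
        else:
            raise ValueError(f"unknown agent_kind {agent_kind!r}")
    return assignment


@dataclass
class BatchResult:
    """Everything a batch run produced: logs, tidy metric tables, traces,
    a replay manifest, and any per-game failures."""

    logs: list[GameLog]
    if_table: pd.DataFrame
    alloc_table: pd.DataFrame
    rating_table: pd.DataFrame
    trace_table: pd.DataFrame
    manifest: dict
    failures: list[tuple[str, str]] = field(default_factory=list)


def run_batch(
    design: StudyDesign,
    params: PolicyParams | None = None,
    agent_kind: str | None = None,
    agent_cfg: AdaptiveAgentConfig | None = None,
    out_dir: str | Path | None = None,
    *,
    with_ratings: bool = True,
) -> BatchResult:
    """Run every game of a design with its own derived seed.

    ``agent_kind`` defaults to nonadaptive for the long design and
    adaptive for the short one. A failing game is logged and skipped;
    the batch continues. With ``out_dir`` set, per-game log directories,
    the tidy metric CSVs and a JSON manifest are written for bit-exact
    replay.
    """
    from . import __version__

    if agent_kind is None:
        agent_kind = "adaptive" if design.study == "study2" else "nonadaptive"
    params = params or PolicyParams()
    agent_cfg = agent_cfg or AdaptiveAgentConfig()

    logs: list[GameLog] = []
    failures: list[tuple[str, str]] = []
    if_frames, alloc_frames, rating_frames, trace_frames = [], [], [], []
    for config in design.configs:
        try:
            assignment = make_policies(config, params, agent_kind, agent_cfg)
            log = run_game(config, assignment, with_ratings=with_ratings)
            game_if = if_table(log)
            game_alloc = allocation_table(log)
            logs.append(log)
            if_frames.append(game_if)
            if not game_alloc.empty:
                alloc_frames.append(game_alloc)
            if log.ratings:
                rs = rating_summary(log.ratings)
                rs.insert(0, "game_id", config.game_id)
                rs.insert(1, "condition", config.condition)
                rating_frames.append(rs)
            seen = set()
            for policy in assignment.values():
                if isinstance(policy, AdaptiveAgentPolicy) and id(policy) not in seen:
                    seen.add(id(policy))
                    trace_frames.append(policy.trace_frame())
        except Exception as exc:  # noqa: BLE001 - batch must survive bad games
            warnings.warn(f"game {config.game_id} failed: {exc}")
            failures.append((config.game_id, str(exc)))

    empty = pd.DataFrame()
    result = BatchResult(
        logs=logs,
        if_table=pd.concat(if_frames, ignore_index=True) if if_frames else empty,
        alloc_table=pd.concat(alloc_frames, ignore_index=True) if alloc_frames else empty,
        rating_table=pd.concat(rating_frames, ignore_index=True) if rating_frames else empty,
        trace_table=pd.concat(trace_frames, ignore_index=True) if trace_frames else empty,
        manifest={
            "study": design.study,
            "version": __version__,
            "agent_kind": agent_kind,
            "params": vars(params),
            "agent_cfg": vars(agent_cfg),
            "games": [
                {"game_id": c.game_id, "condition": c.condition, "seed": c.seed}
                for c in design.configs
            ],
            "failures": failures,
        },
        failures=failures,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for log in logs:
            game_io.write_game_log(log, out / log.config.game_id)
        result.if_table.to_csv(out / "ingroup_favoritism.csv", index=False)
        result.alloc_table.to_csv(out / "normalized_allocations.csv", index=False)
        result.rating_table.to_csv(out / "rating_summaries.csv", index=False)
        result.trace_table.to_csv(out / "agent_decision_trace.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
    return result


def bootstrap_ci(
    values: list[float] | np.ndarray,
    B: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean of
    game-level statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)


def permutation_wave_test(
    wave_a: list[float] | np.ndarray,
    wave_b: list[float] | np.ndarray,
    permutations: int = 10000,
    seed: int | None = None,
) -> float:
    """Two-sided sign-flip permutation p-value for a paired mean difference.

    ``wave_a`` and ``wave_b`` are per-game means at two waves (paired by
    game). All 2^n sign patterns are enumerated when that is within the
    permutation budget; otherwise random sign flips are drawn and the
    observed statistic is counted among them. A single pair is degenerate
    and returns 1.0 with a warning.
    """
    a = np.asarray(wave_a, dtype=float)
    b = np.asarray(wave_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("wave_a and wave_b must be 1-d and paired (same length)")
    if permutations < 100:
        raise ValueError("permutations must be >= 100")
    n = a.size
    if n == 0:
        raise ValueError("empty input")
    if n == 1:
        warnings.warn("only one paired value; permutation test is degenerate")
        return 1.0

    d = a - b
    observed = abs(d.mean())
    tol = 1e-12
    if n <= 20 and 2**n <= permutations:
        signs = np.array(
            [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2**n)]
        )
        stats = np.abs((signs * d).mean(axis=1))
        return float(np.mean(stats >= observed - tol))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(permutations, n))
    stats = np.abs((signs * d).mean(axis=1))
    exceed = int(np.sum(stats >= observed - tol))
    return float((1 + exceed) / (permutations + 1))
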