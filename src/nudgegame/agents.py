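"""Nudge-agent allocation policies.

Two agent designs, both exhibiting outgroup altruism:

* **nonadaptive** — allocates to a uniformly random outgroup member in
  every round;
* **adaptive** — refits a motive model on the public history each round,
  predicts each outgroup human's probability of reciprocating, and
  allocates uniformly among those above a threshold; when no outgroup
  human clears the threshold it falls back to a uniformly random
  ingroup member (never itself). During a short warm-up, before any
  history exists to learn from, it allocates uniformly to the outgroup,
  seeding cross-group reciprocity.

Adaptive agents emit a per-round decision trace (candidate set, chosen
recipient, fallback flag) so every ingroup allocation can be audited
against an empty candidate set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chmm
from .engine import GameState
from .types import PlayerRef


@dataclass(frozen=True)
class AdaptiveAgentConfig:
    """Tunables of the adaptive agent.

    ``reciprocation_threshold`` is the predicted-probability cut-off for
    "likely to reciprocate" (default 0.5, the natural reading);
    ``warmup_rounds`` is the number of initial rounds played uniformly
    toward the outgroup before the model is consulted; ``motive_count``
    is K for the motive model; ``target_outgroup_agents`` widens the
    candidate set to outgroup agents as well as humans (off by default).
    """

    reciprocation_threshold: float = 0.5
    warmup_rounds: int = 1
    motive_count: int = 4
    reciprocation_window: int = 1
    target_outgroup_agents: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.reciprocation_threshold < 1:
            raise ValueError("reciprocation_threshold must lie strictly in (0, 1)")
        if self.warmup_rounds < 1:
            raise ValueError("warmup_rounds must be >= 1")
        if self.motive_count < 1:
            raise ValueError("motive_count must be >= 1")


def nonadaptive_policy(
    state: GameState, agent: PlayerRef, rng: np.random.Generator
) -> PlayerRef:
    """Preprogrammed outgroup altruism: a uniformly random outgroup
    member every round; never self, never ingroup."""
    if agent.kind != "agent":
        raise ValueError(f"{agent.id} is not an agent")
    outgroup = state.outgroup(agent)
    if not outgroup:
        raise ValueError("malformed game: no outgroup members")
    return outgroup[rng.integers(len(outgroup))]


def select_recipient(
    predictions: dict[str, float],
    outgroup_candidates: list[PlayerRef],
    ingroup_others: list[PlayerRef],
    threshold: float,
    rng: np.random.Generator,
) -> tuple[PlayerRef, list[str], bool]:
    """Threshold rule of the adaptive agent.

    Returns (recipient, candidate ids above threshold, fallback flag):
    a uniform draw from the above-threshold candidates when any exist,
    otherwise a uniform draw from the agent's ingroup (excluding itself).
    """
    candidates = [p for p in outgroup_candidates if predictions[p.id] > threshold]
    if candidates:
        chosen = candidates[rng.integers(len(candidates))]
        return chosen, [p.id for p in candidates], False
    chosen = ingroup_others[rng.integers(len(ingroup_others))]
    return chosen, [], True


def adaptive_policy(
    state: GameState,
    agent: PlayerRef,
    model: chmm.MotiveModel | None,
    cfg: AdaptiveAgentConfig,
    rng: np.random.Generator,
) -> tuple[PlayerRef, list[str], bool]:
    """One adaptive-agent decision given an already-fitted motive model.

    Returns (recipient, candidate ids, fallback flag). ``model`` may be
    None only during warm-up (round <= cfg.warmup_rounds), when the
    recipient is a uniformly random outgroup member.
    """
    if agent.kind != "agent":
        raise ValueError(f"{agent.id} is not an agent")
    this_round = state.round + 1
    outgroup = state.outgroup(agent)
    if not outgroup:
        raise ValueError("malformed game: no outgroup members")

    if this_round <= cfg.warmup_rounds or model is None:
        return outgroup[rng.integers(len(outgroup))], [], False

    if cfg.target_outgroup_agents:
        candidates = outgroup
    else:
        candidates = [p for p in outgroup if p.kind == "human"]
    predictions = {
        p.id: chmm.predict_reciprocation(
            model,
            chmm.extract_features(
                state.history, p, this_round, agent, state.config,
                window=cfg.reciprocation_window,
            ),
        )
        for p in candidates
    }
    return select_recipient(
        predictions,
        candidates,
        state.ingroup_others(agent),
        cfg.reciprocation_threshold,
        rng,
    )


class NonadaptiveAgentPolicy:
    """Engine-facing wrapper around :func:`nonadaptive_policy`."""

    def choose(
        self, state: GameState, player: PlayerRef, rng: np.random.Generator
    ) -> PlayerRef:
        return nonadaptive_policy(state, player, rng)


@dataclass
class _SequenceCache:
    """Incrementally grown per-player feature/label sequences.

    Features at round t depend only on history before t, so each round
    appends one entry per player instead of rescanning the whole game.
    Labels (reciprocation at round t) lag one round behind features: the
    outcome of round t is only observable once round t is in the history.
    """

    last_round: int = 0
    features: dict[str, list[chmm.FeatureVector]] = field(default_factory=dict)
    labels: dict[str, list[bool | None]] = field(default_factory=dict)


class AdaptiveAgentPolicy:
    """Adaptive nudge agent: refit each round, predict, threshold, trace.

    One instance may be shared by all agents of the same group (their
    observation of the game is identical); the fitted model is cached
    per round. ``trace`` accumulates one row per decision:
    (round, agent_id, candidates, chosen, fallback).
    """

    def __init__(
        self,
        cfg: AdaptiveAgentConfig | None = None,
        *,
        group: int,
        seed: int | None = None,
    ):
        self.cfg = cfg or AdaptiveAgentConfig()
        self.group = group
        self.seed = seed
        self.trace: list[dict] = []
        self._cache = _SequenceCache()
        self._model_round: int | None = None
        self._model: chmm.MotiveModel | None = None

    def reset(self) -> None:
        self.trace = []
        self._cache = _SequenceCache()
        self._model_round = None
        self._model = None

    # -- model upkeep -------------------------------------------------
    def _extend_cache(self, state: GameState) -> None:
        cache = self._cache
        if not cache.features:
            cache.features = {p.id: [] for p in state.players}
            cache.labels = {p.id: [] for p in state.players}
        focal = next(
            p for p in state.players if p.group == self.group and p.kind == "agent"
        )
        # append features/labels for each completed round not yet processed
        for t in range(cache.last_round + 1, state.round + 1):
            for p in state.players:
                if p.id == focal.id:
                    continue
                cache.features[p.id].append(
                    chmm.extract_features(
                        state.history, p, t, focal, state.config,
                        window=self.cfg.reciprocation_window,
                    )
                )
                cache.labels[p.id].append(
                    chmm.detect_reciprocation(
                        state.history, p, t, self.cfg.reciprocation_window
                    )
                )
        cache.last_round = state.round

    def _model_for(self, state: GameState) -> chmm.MotiveModel:
        this_round = state.round + 1
        if self._model_round == this_round and self._model is not None:
            return self._model
        self._extend_cache(state)
        feats = [seq for seq in self._cache.features.values() if seq]
        labels = [self._cache.labels[pid] for pid, seq in self._cache.features.items() if seq]
        self._model = chmm.fit_motive_model(
            feats, labels, K=self.cfg.motive_count, seed=self.seed
        )
        self._model_round = this_round
        return self._model

    # -- engine interface ----------------------------------------------
    def choose(
        self, state: GameState, player: PlayerRef, rng: np.random.Generator
    ) -> PlayerRef:
        this_round = state.round + 1
        if this_round <= self.cfg.warmup_rounds:
            model = None
        else:
            with warnings.catch_warnings():
                # tiny early histories routinely have < K distinct points
                warnings.simplefilter("ignore", UserWarning)
                model = self._model_for(state)
        recipient, candidates, fallback = adaptive_policy(
            state, player, model, self.cfg, rng
        )
        self.trace.append(
            {
                "game_id": state.config.game_id,
                "round": this_round,
                "agent_id": player.id,
                "candidates": ",".join(candidates),
                "chosen": recipient.id,
                "fallback": fallback,
            }
        )
        return recipient

    def trace_frame(self) -> pd.DataFrame:
        """The decision trace as a tidy table (one row per decision)."""
        return pd.DataFrame(
            self.trace,
            columns=["game_id", "round", "agent_id", "candidates", "chosen", "fallback"],
        )
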