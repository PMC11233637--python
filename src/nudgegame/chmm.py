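"""Cluster hidden Markov model of allocation motives.

Each hidden state ("motive") is a cluster of per-player, per-round
behavioral feature vectors. The model has three parts: the cluster
centers, a row-stochastic transition matrix between motives, and a
Bernoulli reciprocation probability per motive. Fitting is fully
count-based: k-means for the centers, smoothed bigram counts for the
transitions, and smoothed label frequencies for the emissions — the
simplest estimator family consistent with the model class. Prediction
is one step ahead: assign the current features to their nearest motive,
then average the per-motive reciprocation probabilities over one
transition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .types import AllocationEvent, GameConfig, PlayerRef

#: feature order used in every array representation
FEATURE_NAMES = (
    "group_alignment",
    "ingroup_tie",
    "outgroup_tie",
    "wealth",
    "reciprocation_tendency",
)


@dataclass(frozen=True)
class FeatureVector:
    """Behavioral features of one player at the start of one round.

    All components live on [0, 1]-like scales by construction, so the
    cluster geometry is comparable across games without re-scaling:

    * ``group_alignment`` — 1 if the player shares the focal agent's
      group, else 0;
    * ``ingroup_tie`` / ``outgroup_tie`` — shares of the player's past
      non-self allocations by target group (0/0 before the first
      non-self allocation, with ``allocated`` False);
    * ``wealth`` — current token balance over starting tokens;
    * ``reciprocation_tendency`` — share of past reciprocation
      opportunities the player took (prior 0.5 before any opportunity).
    """

    group_alignment: float
    ingroup_tie: float
    outgroup_tie: float
    wealth: float
    reciprocation_tendency: float
    allocated: bool = True

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.group_alignment,
                self.ingroup_tie,
                self.outgroup_tie,
                self.wealth,
                self.reciprocation_tendency,
            ]
        )


@dataclass
class MotiveModel:
    """A fitted cluster-HMM: centers, transitions, emissions."""

    K: int
    centers: np.ndarray  # (K, n_features)
    transitions: np.ndarray  # (K, K), row-stochastic
    emissions: np.ndarray  # (K,), per-motive reciprocation probability
    seed: int | None = None

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.transitions.shape != (self.K, self.K):
            raise ValueError("transition matrix shape mismatch")
        row_sums = self.transitions.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise ValueError(f"transition rows must sum to 1, got {row_sums}")
        if np.any((self.emissions < 0) | (self.emissions > 1)):
            raise ValueError("emissions must lie in [0, 1]")

    def assign_state(self, features: FeatureVector) -> int:
        d = np.linalg.norm(self.centers - features.as_array(), axis=1)
        return int(np.argmin(d))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "K": self.K,
                "centers": self.centers.tolist(),
                "transitions": self.transitions.tolist(),
                "emissions": self.emissions.tolist(),
                "seed": self.seed,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "MotiveModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        return cls(
            K=d["K"],
            centers=np.asarray(d["centers"], dtype=float),
            transitions=np.asarray(d["transitions"], dtype=float),
            emissions=np.asarray(d["emissions"], dtype=float),
            seed=d.get("seed"),
        )


def detect_reciprocation(
    history: list[AllocationEvent],
    player: PlayerRef,
    round: int,
    window: int = 1,
) -> bool | None:
    """Did ``player`` reciprocate at ``round``?

    True iff the player's round-``round`` allocation went to someone who
    gave to the player within the ``window`` preceding rounds. Returns
    ``None`` (undefined opportunity) when nobody gave to the player in
    the window or when ``round < 2``; undefined rounds are excluded from
    tendency denominators, they are not failures to reciprocate.
    """
    if round < 2:
        return None
    benefactors = {
        e.allocator.id
        for e in history
        if e.recipient.id == player.id
        and e.allocator.id != player.id
        and round - window <= e.round <= round - 1
    }
    if not benefactors:
        return None
    for e in history:
        if e.round == round and e.allocator.id == player.id:
            return e.recipient.id in benefactors
    return None  # player has no allocation at that round (incomplete history)


def extract_features(
    history: list[AllocationEvent],
    player: PlayerRef,
    round: int,
    focal_agent: PlayerRef,
    config: GameConfig,
    *,
    window: int = 1,
) -> FeatureVector:
    """Features of ``player`` at the start of ``round``, from the focal
    agent's perspective; computed from events strictly before ``round``.

    Cold start (round 1, empty history): ties 0/0 flagged unallocated,
    wealth 1.0, tendency prior 0.5.
    """
    if round < 1:
        raise ValueError("round must be >= 1")

    given_in = given_out = received = given_all = 0
    for e in history:
        if e.round >= round:
            continue
        if e.allocator.id == player.id:
            given_all += 1
            if e.recipient.id != player.id:
                if e.recipient.group == player.group:
                    given_in += 1
                else:
                    given_out += 1
        if e.recipient.id == player.id:
            received += 1

    nonself = given_in + given_out
    if nonself:
        ingroup_tie = given_in / nonself
        outgroup_tie = given_out / nonself
        allocated = True
    else:
        ingroup_tie = outgroup_tie = 0.0
        allocated = False

    balance = config.starting_tokens + received - given_all
    wealth = balance / config.starting_tokens

    opportunities = taken = 0
    for t in range(2, round):
        r = detect_reciprocation(history, player, t, window)
        if r is None:
            continue
        opportunities += 1
        taken += int(r)
    tendency = taken / opportunities if opportunities else 0.5

    return FeatureVector(
        group_alignment=1.0 if player.group == focal_agent.group else 0.0,
        ingroup_tie=ingroup_tie,
        outgroup_tie=outgroup_tie,
        wealth=wealth,
        reciprocation_tendency=tendency,
        allocated=allocated,
    )


def fit_motive_model(
    feature_sequences: Sequence[Sequence[FeatureVector]],
    label_sequences: Sequence[Sequence[bool | None]],
    K: int = 4,
    seed: int | None = None,
    *,
    n_restarts: int = 10,
) -> MotiveModel:
    """Fit a motive model from aligned per-player sequences.

    ``feature_sequences[p][t]`` are player ``p``'s features at their
    ``t``-th observed round and ``label_sequences[p][t]`` the matching
    reciprocation outcome (``None`` = no opportunity, excluded from the
    emission counts but kept in the state chain). Centers come from
    seeded k-means with restarts; transitions are add-one-smoothed bigram
    counts of nearest-center state sequences; emissions are add-one-
    smoothed per-state reciprocation frequencies.
    """
    if len(feature_sequences) != len(label_sequences):
        raise ValueError("feature and label sequences differ in number")
    flat_features = [f for seq in feature_sequences for f in seq]
    flat_labels = [l for seq in label_sequences for l in seq]
    if len(flat_features) != len(flat_labels):
        raise ValueError("feature and label sequences differ in length")
    if not flat_features:
        raise ValueError("empty input: no feature vectors to fit")

    X = np.vstack([f.as_array() for f in flat_features])
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < K:
        warnings.warn(
            f"only {n_distinct} distinct feature points; reducing K from "
            f"{K} to {n_distinct}"
        )
        K = n_distinct

    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
    km.fit(X)
    centers = km.cluster_centers_

    def nearest(x: np.ndarray) -> int:
        return int(np.argmin(np.linalg.norm(centers - x, axis=1)))

    trans_counts = np.zeros((K, K))
    emit_true = np.zeros(K)
    emit_total = np.zeros(K)
    for feats, labels in zip(feature_sequences, label_sequences):
        states = [nearest(f.as_array()) for f in feats]
        for s1, s2 in zip(states[:-1], states[1:]):
            trans_counts[s1, s2] += 1
        for s, lab in zip(states, labels):
            if lab is None:
                continue
            emit_total[s] += 1
            emit_true[s] += int(lab)

    transitions = (trans_counts + 1.0) / (trans_counts + 1.0).sum(axis=1, keepdims=True)
    emissions = (emit_true + 1.0) / (emit_total + 2.0)

    model = MotiveModel(
        K=K, centers=centers, transitions=transitions, emissions=emissions, seed=seed
    )
    model.validate()
    return model


def predict_reciprocation(model: MotiveModel, current_features: FeatureVector) -> float:
    """One-step-ahead reciprocation probability for a player whose current
    features are given: sum over next motives of transition probability
    times that motive's reciprocation probability."""
    model.validate()
    s = model.assign_state(current_features)
    return float(model.transitions[s] @ model.emissions)


def forward_filter(
    model: MotiveModel, observations: Sequence[bool]
) -> np.ndarray:
    """Posterior distribution over motives after a Bernoulli observation
    sequence (standard forward recursion, uniform initial distribution).

    Returns the filtered posterior at the final observation; it sums to
    1. A sequence with zero total likelihood yields a uniform posterior
    with a warning.
    """
    model.validate()
    obs = list(observations)
    if not obs:
        raise ValueError("empty observation sequence")

    def b(o: bool) -> np.ndarray:
        return model.emissions if o else 1.0 - model.emissions

    alpha = np.full(model.K, 1.0 / model.K) * b(obs[0])
    for o in obs[1:]:
        alpha = (alpha @ model.transitions) * b(o)
    total = alpha.sum()
    if total <= 0:
        warnings.warn("zero likelihood for observation sequence; uniform posterior")
        return np.full(model.K, 1.0 / model.K)
    return alpha / total


def sample_motive_sequences(
    model: MotiveModel,
    n_sequences: int,
    length: int,
    rng: np.random.Generator,
    *,
    feature_noise: float = 0.05,
) -> tuple[list[list[FeatureVector]], list[list[bool]], list[list[int]]]:
    """Simulate sequences from a motive model (for parameter-recovery
    studies): hidden motives follow the transition matrix from a uniform
    start, features are the motive's center plus truncated Gaussian
    noise, observations are Bernoulli(emission of the motive).

    Returns (feature sequences, observation sequences, true state paths).
    """
    model.validate()
    feats_all, obs_all, states_all = [], [], []
    for _ in range(n_sequences):
        feats, obs, states = [], [], []
        s = int(rng.integers(model.K))
        for _t in range(length):
            x = np.clip(
                model.centers[s] + rng.normal(0, feature_noise, model.centers.shape[1]),
                0.0,
                1.5,
            )
            feats.append(
                FeatureVector(
                    group_alignment=float(x[0]),
                    ingroup_tie=float(x[1]),
                    outgroup_tie=float(x[2]),
                    wealth=float(x[3]),
                    reciprocation_tendency=float(x[4]),
                )
            )
            obs.append(bool(rng.random() < model.emissions[s]))
            states.append(s)
            s = int(rng.choice(model.K, p=model.transitions[s]))
        feats_all.append(feats)
        obs_all.append(obs)
        states_all.append(states)
    return feats_all, obs_all, states_all
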