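"""Synthetic human participants.

The allocation policy is a softmax choice over the eight players whose
utilities encode the three behavioral regularities the analyses assume:

* **ingroup bias** — a constant bonus for members of one's own group
  (self included);
* **reciprocity** — a bonus proportional to how often a candidate gave
  to the focal player within a short sliding window of recent rounds;
* **norm enforcement** — a penalty for ingroup members whose past giving
  went mostly to the outgroup ("defectors"), capturing the withdrawal of
  cooperation from perceived norm violators.

Self-giving enters through a separate multiplicative weight, and an
optional imitation term (off by default) lets ingroup peers' recent
outgroup giving pull the focal player toward the outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .engine import GameState
from .types import AllocationEvent, PlayerRef, RatingRecord


@dataclass(frozen=True)
class PolicyParams:
    """Parameters of the synthetic human allocation policy.

    Defaults are calibrated so that an agent-free population opens at a
    mean ingroup-favoritism ratio near 0.67 and stays in a clearly
    ingroup-favoring band — biased toward the ingroup but responsive to
    reciprocity. The calibration is a documented modeling choice, not a
    fit to any empirical dataset.

    Attributes
    ----------
    ingroup_bias:
        Constant utility bonus for same-group candidates (self included).
    reciprocity_weight:
        Utility per token received from a candidate within the recent
        window.
    norm_enforcement:
        Utility penalty applied to ingroup candidates whose outgroup
        share of past giving exceeds ``defector_threshold``.
    defector_threshold:
        Outgroup share above which an ingroup member counts as a norm
        violator.
    self_weight:
        Multiplicative weight on choosing oneself (enters the utility as
        ``log(self_weight)``); values below 1 make self-giving rare.
    temperature:
        Softmax temperature; lower values make choices more deterministic.
    reciprocity_window:
        Number of recent completed rounds over which received tokens are
        counted.
    reciprocity_cap:
        Cap on the counted tokens per benefactor within the window (1 =
        a recent-benefactor indicator). The cap keeps mutual dyads from
        escalating into near-deterministic exchange loops.
    imitation_weight:
        Optional bonus to outgroup candidates proportional to the share
        of ingroup peers' recent giving that went to the outgroup;
        disabled (0) by default because neither study found imitation.
    """

    ingroup_bias: float = 1.0
    reciprocity_weight: float = 1.5
    norm_enforcement: float = 1.0
    defector_threshold: float = 0.5
    self_weight: float = 0.3
    temperature: float = 1.0
    reciprocity_window: int = 3
    reciprocity_cap: int = 2
    imitation_weight: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "ingroup_bias",
            "reciprocity_weight",
            "norm_enforcement",
            "self_weight",
            "imitation_weight",
        ):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val}")
        if self.self_weight <= 0:
            raise ValueError("self_weight must be > 0")
        if not 0 <= self.defector_threshold <= 1:
            raise ValueError("defector_threshold must lie in [0, 1]")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


def outgroup_share(
    history: list[AllocationEvent], player: PlayerRef, upto_round: int
) -> float:
    """Fraction of a player's non-self allocations before ``upto_round``
    that went to the outgroup; 0.0 when the player has not yet allocated
    to anyone else."""
    if upto_round < 1:
        raise ValueError("upto_round must be >= 1")
    out = total = 0
    for e in history:
        if e.round >= upto_round or e.allocator.id != player.id:
            continue
        if e.recipient.id == e.allocator.id:
            continue
        total += 1
        if e.recipient.group != player.group:
            out += 1
    return out / total if total else 0.0


def recipient_weights(
    state: GameState, focal: PlayerRef, params: PolicyParams
) -> np.ndarray:
    """Choice probabilities over ``state.players`` (in roster order).

    Utilities: ingroup bonus + reciprocity toward recent benefactors -
    norm-enforcement penalty on ingroup defectors + log(self_weight) for
    oneself; probabilities are softmax(u / temperature) and sum to 1.
    """
    if focal.kind != "human":
        raise ValueError(f"recipient_weights is a human policy; {focal.id} is an agent")

    recent = state.recent_events(params.reciprocity_window)
    received_from: dict[str, int] = {}
    for e in recent:
        if e.recipient.id == focal.id and e.allocator.id != focal.id:
            received_from[e.allocator.id] = received_from.get(e.allocator.id, 0) + 1

    if params.imitation_weight > 0:
        peer_total = peer_out = 0
        for e in recent:
            if (
                e.allocator.group == focal.group
                and e.allocator.id != focal.id
                and e.recipient.id != e.allocator.id
            ):
                peer_total += 1
                if e.recipient.group != focal.group:
                    peer_out += 1
        peer_outgroup_share = peer_out / peer_total if peer_total else 0.0
    else:
        peer_outgroup_share = 0.0

    utilities = np.zeros(len(state.players))
    for j, cand in enumerate(state.players):
        u = 0.0
        if cand.group == focal.group:
            u += params.ingroup_bias
        else:
            u += params.imitation_weight * peer_outgroup_share
        u += params.reciprocity_weight * min(
            received_from.get(cand.id, 0), params.reciprocity_cap
        )
        if (
            params.norm_enforcement > 0
            and cand.group == focal.group
            and cand.id != focal.id
        ):
            # engine tallies equal outgroup_share(state.history, cand, upto)
            given_in = state.given_ingroup[cand.id]
            given_out = state.given_outgroup[cand.id]
            total_given = given_in + given_out
            share = given_out / total_given if total_given else 0.0
            if share > params.defector_threshold:
                u -= params.norm_enforcement
        if cand.id == focal.id:
            u += np.log(params.self_weight)
        utilities[j] = u

    return softmax(utilities / params.temperature)


def sample_allocation(
    weights: np.ndarray, players: list[PlayerRef], rng: np.random.Generator
) -> PlayerRef:
    """Draw a recipient from a categorical distribution over ``players``."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(players):
        raise ValueError("weights and players differ in length")
    if np.any(weights < 0):
        raise ValueError("negative weight")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {weights.sum():.6f}, not 1")
    idx = rng.choice(len(players), p=weights / weights.sum())
    return players[idx]


class HumanPolicy:
    """Softmax allocation policy for a synthetic human participant."""

    def __init__(self, params: PolicyParams | None = None):
        self.params = params or PolicyParams()

    def choose(
        self, state: GameState, player: PlayerRef, rng: np.random.Generator
    ) -> PlayerRef:
        weights = recipient_weights(state, player, self.params)
        return sample_allocation(weights, state.players, rng)


def generate_ratings(
    players: list[PlayerRef],
    events: list[AllocationEvent],
    rng: np.random.Generator,
    *,
    fairness_noise: float = 0.5,
    humanness_noise: float = 0.8,
) -> list[RatingRecord]:
    """Synthetic post-game 1-5 ratings by every human of every other player.

    Fairness tracks how much of the target's non-self giving went to the
    rater's own group (raters find group-serving play fair), mapped onto
    the 1-5 scale with Gaussian noise. Humanness is noise around the
    scale midpoint: embedded agents are not behaviorally identifiable to
    the synthetic raters, mirroring a failed agent-detection check.
    """
    given_to_group: dict[str, list[int]] = {p.id: [0, 0] for p in players}
    for e in events:
        if e.recipient.id == e.allocator.id:
            continue
        given_to_group[e.allocator.id][e.recipient.group - 1] += 1

    ratings: list[RatingRecord] = []
    for rater in players:
        if rater.kind != "human":
            continue
        for target in players:
            if target.id == rater.id:
                continue
            g1, g2 = given_to_group[target.id]
            total = g1 + g2
            share = (g1 if rater.group == 1 else g2) / total if total else 0.5
            fair = int(np.clip(np.rint(1 + 4 * share + rng.normal(0, fairness_noise)), 1, 5))
            human = int(np.clip(np.rint(3 + rng.normal(0, humanness_noise)), 1, 5))
            ratings.append(RatingRecord(rater, target, "fairness", fair))
            ratings.append(RatingRecord(rater, target, "humanness", human))
    return ratings
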