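# Methods

## The game

Eight players in two groups of four exchange tokens over `R` rounds
(30 or 15 in the canned designs). Every round each player allocates
exactly one token to any player, self included; a transfer adds one
token to the recipient and removes one from the allocator, so the total
is conserved and, because starting tokens ≥ rounds, no balance can go
negative. Play is **simultaneous**: all eight decisions are computed
from the public state at the end of the previous round and applied
together. This removes any dependence on intra-round ordering, matching
a platform that reveals exchanges only at the end of each round. An
optional unscored warm-up phase (`trial_rounds`) can precede the game;
its events are discarded entirely and never reach a metric. Rounds are
1-based throughout.

## Synthetic participants

Human allocation is a softmax choice over the eight players with
utilities

```
u_j = b·[j ingroup]
    + r·min(g_j, c)
    − e·[j ingroup, j ≠ self, outgroup-share(j) > d]
    + log(s)·[j = self]
    (+ m·peer-outgroup-share·[j outgroup])
P(j) ∝ exp(u_j / τ)
```

where `g_j` is the number of tokens `j` gave the focal player within the
last `W` completed rounds and `outgroup-share(j)` is the fraction of
`j`'s past non-self allocations that crossed the group boundary.

Parameters, defaults, and rationale:

| parameter | default | meaning |
|---|---|---|
| `ingroup_bias` b | 1.0 | constant ingroup bonus; alone it gives a round-one ingroup choice share of 3e/(3e+4) ≈ 0.67 |
| `reciprocity_weight` r | 1.5 | bonus per recent received token |
| `reciprocity_window` W | 3 rounds | reciprocity is short-horizon |
| `reciprocity_cap` c | 2 | cap on counted tokens per benefactor |
| `norm_enforcement` e | 1.0 | penalty on ingroup "defectors" |
| `defector_threshold` d | 0.5 | outgroup share that marks a defector |
| `self_weight` s | 0.3 | multiplicative self-giving weight |
| `temperature` τ | 1.0 | choice noise |
| `imitation_weight` m | 0.0 | off by default (see below) |

Two choices deserve comment. First, the reciprocity term is **capped**:
pilot batches with an unbounded count let mutual ingroup dyads escalate
into near-deterministic exchange loops, driving agent-free populations
to favoritism ratios above 0.9; with the cap the agent-free population
opens near 0.67 and stays in a clearly ingroup-favoring but non-extreme
band, which is the regime the analyses assume. The calibration was fixed
once, from agent-free and agent-present pilot batches, and is a modeling
choice — it is not fitted to any empirical data, and no claim is made
that the synthetic policy matches human participants quantitatively.
Second, an **imitation** term (outgroup bonus proportional to ingroup
peers' recent outgroup giving) exists behind a flag but defaults to off:
the empirical studies this framework emulates found reciprocity, not
imitation, to be the operative mechanism, so the default population
should not bake imitation in; the flag supports counterfactuals.

Synthetic **ratings** (1–5) are generated post-game: a rater's fairness
judgment of a target maps the share of the target's non-self giving that
reached the rater's group onto the scale (plus Gaussian noise, rounded
and clipped), so outgroup-favoring ingroup members are judged unfair by
their own group. Humanness is noise around the midpoint — the synthetic
raters cannot identify agents behaviorally, emulating a failed
agent-detection manipulation check.

## Agents

The **nonadaptive** agent allocates to a uniformly random outgroup
member every round — its outgroup share is exactly 1 by construction. It
never self-allocates.

The **adaptive** agent, each round after a one-round warm-up:

1. refits the motive model on the full public history (agents of the
   same group share one model — they observe identical states);
2. extracts current features for each outgroup human and predicts the
   one-step-ahead reciprocation probability;
3. allocates uniformly among those with prediction strictly above
   `reciprocation_threshold` (default 0.5 — the natural reading of
   "likely to reciprocate");
4. if none clears the threshold, falls back to a uniformly random
   ingroup member other than itself.

During warm-up (default 1 round, before any history exists) it allocates
uniformly to the outgroup, seeding cross-group reciprocity in line with
its purpose. Candidates are restricted to outgroup *humans* by default
(`target_outgroup_agents` widens this). Every decision appends a trace
row (round, agent, candidate set, chosen recipient, fallback flag), so
ingroup allocations can be audited: they occur exactly in empty-candidate
rounds.

## The cluster-HMM

Features per player per round, all on [0, 1]-like scales by
construction (no z-scoring, keeping cluster geometry comparable across
games): group alignment with the focal agent, ingroup/outgroup tie
shares of past non-self giving, wealth (balance / starting tokens), and
reciprocation tendency (share of past defined opportunities taken,
prior 0.5). Cold-start values at round 1: ties 0/0 (flagged
unallocated), wealth 1.0, tendency 0.5.

A **reciprocation opportunity** at round `t` exists when someone gave to
the player within rounds `[t − window, t − 1]` (window default 1: an
immediate-response reading); the label is true when the player's round-
`t` allocation went to such a benefactor, and **undefined** (excluded
from denominators, distinct from false) when there was no benefactor.

Fitting is count-based: k-means (seeded, 10 restarts; K default 4,
reduced with a warning when there are fewer distinct points) gives the
motive centers; nearest-center state sequences give bigram transition
counts with add-one smoothing; emissions are add-one-smoothed
reciprocation frequencies per state. No Baum–Welch re-estimation is
performed — with fully observed feature sequences the latent states are
pinned by the clustering, and the count estimator is consistent for the
model class. The forward filter is the standard recursion with Bernoulli
emissions and a uniform initial distribution (no better-informed prior
exists at round 1); a zero-likelihood sequence returns a uniform
posterior with a warning. Prediction is invariant to permutations of
motive labels.

## Metrics

Ingroup favoritism follows the ratio definition exactly (self-giving
excluded, agents excluded, undefined when a wave has no non-self
allocations; undefined values propagate as missing and are excluded from
aggregation — a ratio has no 0/0 convention). Normalized allocation
interprets `N_x` as the per-target count of eligible human allocators —
the only reading consistent with the 3/3/3/2 worked example for a
3-human/1-agent group — and divides additionally by rounds and by the
number of targets in the category, making ratios comparable across the
30- and 15-round designs and across categories of different sizes.
Aggregation across games always reports game-level means: the game is
the replication unit.

## Designs, seeding, inference

The long design crosses five agent placements (1:0, 2:0, 1:1, 2:1, 2:2)
with 10 replicated games (30 rounds, 6-round waves, 30 tokens: 280
humans, 120 agents); the short design crosses three (null, 2:0, 2:2)
with 20 games (15 rounds, 5-round waves, 40 tokens: 360 humans, 120
agents). Per-game seeds derive from the master seed via spawn keys
(`SeedSequence(master, spawn_key=(i,))`), so extending a design never
perturbs earlier games; batches are byte-identical under a fixed master
seed.

Inference over replicated games is resampling-based: percentile
bootstrap confidence intervals for game-level means, and two-sided
sign-flip permutation tests for paired wave contrasts (exhaustive
enumeration when 2^n fits the permutation budget, Monte Carlo with the
observed statistic counted otherwise). Hierarchical mixed-effects
modeling with autoregressive round structure is deliberately out of
scope — the emitted tidy tables (one row per game/condition/group/wave)
are designed so such models can be fitted downstream with standard
tools.

## Problem sizes in the test suite

Directional end-to-end checks run 20 batch replicates at the canned
design sizes (60 short-design games or 50 long-design games per
replicate); parameter recovery uses 20 generator seeds with 500 observed
rounds each; oracle-equivalence suites use 1,000 random toy event lists
and exhaustive path enumeration up to K = 3, length 6. These sizes give
the stochastic checks comfortable power while keeping the full suite
around three minutes on one CPU.

## What the synthetic population does and does not show

The generator emulates the statistical structure the analyses assume —
ingroup-biased allocation, short-horizon reciprocity, norm enforcement —
not fitted human behavior. Passing directional checks demonstrates the
pipeline's internal consistency: that the metrics, agents and designs
interact as intended when the assumed mechanisms are present. It says
nothing about effect sizes in real populations, and empirical quantities
that depend on real participants (mean ratings, fitted model tables)
are intentionally not reproduced. Other known limitations: the softmax
policy has no individual heterogeneity (all humans share one parameter
set); the adaptive agent refits from scratch each round rather than
carrying posterior beliefs across rounds; and the motive model's K,
features and window are configuration choices, not estimates.
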