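"""Fit a motive model to one game and predict reciprocation.

Simulates a single 2:0 game, builds per-player feature/label sequences
from the public history, fits the cluster-HMM, and prints its parts plus
a one-step-ahead reciprocation prediction for each outgroup human.
"""

import numpy as np

from nudgegame import (
    GameConfig,
    detect_reciprocation,
    extract_features,
    fit_motive_model,
    make_players,
    make_policies,
    predict_reciprocation,
    run_game,
)

cfg = GameConfig(
    game_id="demo",
    condition="2:0",
    rounds=15,
    starting_tokens=40,
    agents_per_group=(2, 0),
    wave_length=5,
    seed=11,
)
log = run_game(cfg, make_policies(cfg, agent_kind="adaptive"), with_ratings=False)
agent = next(p for p in log.players if p.kind == "agent")

features, labels = [], []
for p in log.players:
    if p.id == agent.id:
        continue
    features.append(
        [extract_features(log.events, p, t, agent, cfg) for t in range(1, 16)]
    )
    labels.append([detect_reciprocation(log.events, p, t) for t in range(1, 16)])

model = fit_motive_model(features, labels, K=4, seed=0)
print(f"Motive count K = {model.K}")
print("Transition matrix (rows sum to 1):")
print(np.round(model.transitions, 3))
print("Per-motive reciprocation probabilities:", np.round(model.emissions, 3))

print("\nOne-step-ahead reciprocation predictions (outgroup humans):")
for p in log.players:
    if p.group != agent.group and p.kind == "human":
        f = extract_features(log.events, p, 16, agent, cfg)
        print(f"  {p.id}: {predict_reciprocation(model, f):.3f}")
print(
    "\nEach motive is a cluster of behavioral features (ties, wealth,"
    "\nreciprocation tendency); the prediction averages per-motive"
    "\nreciprocation probabilities over one motive transition."
)
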