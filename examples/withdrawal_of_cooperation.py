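"""Measure withdrawal of cooperation from ingroup agents.

Runs the five-condition long design (nonadaptive agents, 30 rounds) and
compares normalized allocation to ingroup humans vs ingroup agents.
"""

import numpy as np

from nudgegame import build_study1_design, run_batch, withdrawal_contrast
from nudgegame.metrics import AbsentCategoryError

design = build_study1_design(seed=3)
batch = run_batch(design)

contrasts = []
for log in batch.logs:
    try:
        contrasts.extend(withdrawal_contrast(log).values())
    except AbsentCategoryError:  # groups without agents are unmeasurable
        continue

contrasts = np.array(contrasts)
print(f"Measurable (game, group) cells: {len(contrasts)}")
print(f"Mean withdrawal contrast: {contrasts.mean():+.3f}")
print(f"Share of cells with positive contrast: {(contrasts > 0).mean():.2f}")
print(
    "\nThe contrast is normalized allocation (n_x / N_x, per round and per"
    "\ntarget) to ingroup humans minus ingroup agents. Positive values mean"
    "\nhumans withheld tokens from the always-outgroup-giving agents in their"
    "\nown group — norm enforcement against perceived ingroup defectors."
)
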