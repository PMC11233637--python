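"""Run the three-condition adaptive-agent design and summarize the nudge.

Builds the 60-game short design (null / 2:0 / 2:2, 15 rounds, 40
tokens), simulates it with adaptive agents against the default synthetic
population, and prints mean ingroup favoritism per condition and wave
with a bootstrap confidence interval for the final-wave contrast.
"""

import numpy as np

from nudgegame import bootstrap_ci, build_study2_design, run_batch

design = build_study2_design(seed=7)
batch = run_batch(design)

game_means = (
    batch.if_table.groupby(["condition", "game_id", "wave"])["if_value"]
    .mean()
    .reset_index()
)
print("Mean ingroup favoritism (IF) by condition and wave:")
print(
    game_means.groupby(["condition", "wave"])["if_value"].mean().unstack().round(3)
)

final = game_means[game_means.wave == 3]
null_vals = final[final.condition == "null"]["if_value"].to_numpy()
nudged_vals = final[final.condition == "2:0"]["if_value"].to_numpy()
diff = null_vals.mean() - nudged_vals.mean()
lo, hi = bootstrap_ci(null_vals, seed=1)
print(f"\nFinal-wave IF, null condition: {null_vals.mean():.3f} (95% CI {lo:.3f}-{hi:.3f})")
print(f"Final-wave IF, condition 2:0: {nudged_vals.mean():.3f}")
print(f"Null minus 2:0: {diff:+.3f}")
print(
    "\nIF is the share of a human's non-self allocations that stayed in their"
    "\nown group (0.5 = group-blind). A positive null-minus-2:0 gap means the"
    "\noutgroup-altruistic agents pulled allocations across the group boundary."
)
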