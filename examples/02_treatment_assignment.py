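"""Derive treatment-assignment rules from a fitted tree.

After pruning, each leaf carries a subgroup label; routing a new
participant's baseline covariates down the tree yields the treatment the
model considers better for people like them.
"""

import pandas as pd

from pyquint import ScenarioSpec, assign_new, generate, grow, prune, resolve_control

dataset = generate(ScenarioSpec(seed=7))
control = resolve_control(dataset, maxl=4, B=25, seed=3)
fit = grow(dataset, control)
pruned = prune(fit, dataset, control)
tree = pruned.tree

new_patients = pd.DataFrame(
    {"x1": [-1.2, 0.9, 0.0], "x2": [0.3, -0.5, 1.1], "x3": [0.0, 0.0, 0.0]}
)
for (leaf, subgroup), (_, row) in zip(assign_new(tree, new_patients), new_patients.iterrows()):
    advice = {
        "P1": "treatment 1 preferred",
        "P2": "treatment 2 preferred",
        "P3": "no clear preference",
    }[subgroup]
    print(f"x1={row.x1:+.1f}: {leaf}, subgroup {subgroup} -> {advice}")
print("\nRows with the splitter at or below the split point go left; the")
print("subgroup label is the class the leaf received during fitting.")
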