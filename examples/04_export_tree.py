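"""Serialize a fitted tree: lossless JSON and Graphviz DOT.

The DOT text colors leaves by subgroup (P1 green, P2 red, P3 grey) and
prints each leaf's effect size with a 95% confidence interval; render it
with any Graphviz installation (``dot -Tpdf``).
"""

import json

from pyquint import ScenarioSpec, export_tree, generate, grow, resolve_control, tree_from_dict

dataset = generate(ScenarioSpec(n=200, seed=5))
control = resolve_control(dataset, maxl=3, bootstrap=False)
tree = grow(dataset, control).final_tree

payload = export_tree(tree, "json")
restored = tree_from_dict(json.loads(payload))
print(f"JSON round-trip intact: {restored.assignment.labels == tree.assignment.labels}")

print("\nDOT export:\n")
print(export_tree(tree, "dot"))
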