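"""Keystone identification by weighted topological importance (WI^3).

WI^3 averages a node's one-, two- and three-step interaction effects, with
one-step effects proportional to edge-weight shares.  Keystones are nodes
with WI^3 > 1 (expanded to >= 1 when fewer than six qualify); their
interaction class is the sign of their summed incident weights, and their
preferred season comes from the relative-abundance or z-score rule.
"""

import networkx as nx
import numpy as np

from sodanet import call_keystones, keystone_sign, preferred_season, topological_importance

# a hand-built star: one hub with five leaves, mixed interaction signs
g = nx.Graph()
for i, w in enumerate([0.9, 0.8, -0.7, 0.9, -0.6]):
    g.add_edge("hub", f"partner{i}", weight=w)

wi = topological_importance(g, steps=3)
keystones = call_keystones(wi)
print("node        WI^3   keystone  sign_class")
for node in sorted(g.nodes, key=lambda n: -wi[n]["wi"]):
    print(
        f"{node:10s}  {wi[node]['wi']:5.2f}  {str(node in keystones):8s}  "
        f"{keystone_sign(g, node)}"
    )
# the hub's WI^3 far exceeds 1 because each leaf's entire interaction budget
# points at it; leaves split theirs and stay below the keystone threshold

# season preference for a spring-blooming OTU (14 fortnightly samples)
labels = ["spring"] * 4 + ["summer"] * 6 + ["autumn"] * 4
series = np.zeros(14)
series[:4] = 0.5  # 50% relative abundance in spring, absent elsewhere
print(f"\nspring bloomer, relabund rule: {preferred_season(series, labels, 'relabund')}")
print(f"spring bloomer, zscore rule:   {preferred_season(series, labels, 'zscore')}")
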