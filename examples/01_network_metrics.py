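"""Build a small plant-pollinator network and compute its topology metrics.

Shows the four network attributes (size S, asymmetry A, connectance C,
nestedness NODF), the three centralities used to rank species for
reintroduction, and the one-mode projection with its beta_eff summary.
"""

import numpy as np

import ecorestore as er

# A nested 4x5 network: generalist plants interact with generalist
# pollinators, specialists only with generalists (classic nested structure).
incidence = np.array([
    [1, 1, 1, 1, 1],
    [1, 1, 1, 0, 0],
    [1, 1, 0, 0, 0],
    [1, 0, 0, 0, 0],
])
net = er.BipartiteNetwork(
    plant_labels=("p1", "p2", "p3", "p4"),
    pollinator_labels=("a1", "a2", "a3", "a4", "a5"),
    incidence=incidence,
)

att = er.attributes(net)
print(f"S = {att.size_S} species, A = {att.asymmetry_A:.2f}, "
      f"C = {att.connectance_C:.3f}, NODF = {att.nestedness_NODF:.2f}")

for measure in ("degree", "closeness", "betweenness"):
    ranking = er.centrality(net, measure).ranked()
    print(f"{measure:<11} ranking: {ranking[:4]}")

proj = er.project(net, side="plants")
print(f"plant projection beta_eff = {er.beta_eff(proj):.3f}")
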