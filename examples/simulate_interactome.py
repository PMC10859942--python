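"""Generate a synthetic aggregate interactome and recover its planted hubs.

Grows a 200-protein network by preferential attachment, boosts 10 random
proteins into the major-hub band (50-99 interactions), adds 100 noise
interactions, then checks how many planted hubs the LOVO ranking recovers
in its top 10 -- the ground-truth version of asking whether leave-one-out
analysis finds the proteins that hold an aggregate together.
"""

from looa import (
    HubGraphSpec,
    classify_hubs,
    generate_hub_graph,
    lovo_deltas,
    score_influence,
)

spec = HubGraphSpec(
    n_vertices=200,
    n_planted_hubs=10,
    hub_degree_range=(50, 99),
    attachment_exponent=1.0,
    noise_edges=100,
    seed=7,
)
graph, hubs = generate_hub_graph(spec)
census = {}
for cls in classify_hubs(graph).values():
    census[cls] = census.get(cls, 0) + 1
print(f"{graph.number_of_nodes()} proteins, {graph.number_of_edges()} interactions")
print(f"hub census: {census}")

result = score_influence(lovo_deltas(graph), graph=graph, top_n=10)
recovered = set(result.ranking.index) & set(hubs)
print(result.ranking.round(2))
print()
print(f"planted hubs recovered in top 10: {len(recovered)}/{len(hubs)}")
print("high recovery means topology alone identifies the planted anchors.")
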