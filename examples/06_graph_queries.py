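"""Path queries, common regulators, and attribute search on a mixed network.

Builds a small heterogeneous network (directed TF-DNA edges plus undirected
protein-protein interactions) and runs the pathway-wizard-style queries.
"""

from bionetkit import (
    InteractionRecord,
    Network,
    attribute_search,
    common_regulators,
    common_targets,
    connect_to_pathways,
    find_paths,
)

net = Network([
    InteractionRecord("CREB", "g1", "tf_dna", directed=True, p_value=2e-4),
    InteractionRecord("CREB", "g2", "tf_dna", directed=True, p_value=8e-4),
    InteractionRecord("NRSF", "g1", "tf_dna", directed=True, p_value=5e-4),
    InteractionRecord("NRSF", "g2", "tf_dna", directed=True, p_value=4e-2),
    InteractionRecord("GATA1", "g2", "tf_dna", directed=True, p_value=1e-5),
    InteractionRecord("CREB", "NRSF", "ppi", directed=False),
    InteractionRecord("g1", "g2", "coexpression", directed=False),
])

paths = find_paths(net, {"GATA1"}, {"g1"}, max_len=2, direction="either")
print("paths GATA1 -> g1 (length <= 2, direction relaxed):")
for p in paths:
    print("  " + " -> ".join(p))

print("common regulators of {g1, g2}:", sorted(common_regulators(net, {"g1", "g2"})))
print("common targets of {CREB, NRSF}:", sorted(common_targets(net, {"CREB", "NRSF"})))

strong = attribute_search(
    net, "(relation_type = tf_dna) AND (p_value < 1e-3)")
print("tf_dna edges with p < 1e-3:",
      [(e.source_id, e.target_id) for e in strong])

pathways = connect_to_pathways(
    {"g1", "g2"}, {"stress response": {"g1", "g2", "g9"},
                   "cell cycle": {"g7", "g8"}})
for row in pathways:
    print(f"pathway overlap: {row['pathway']} k={row['k']}/{row['M']} "
          f"p={row['p']:.3g}")
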