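"""Draw the TOM-thresholded graph of a module, rank hubs, and propose
annotations for unknown features from their identified neighbours.

Edges are kept only where TOM exceeds the threshold (0.13 by default); the
hub metabolite is the member with the largest weighted degree over those
edges.
"""

from metabonet import (DetectionConfig, NetworkConfig, adjacency,
                       correlation_matrix, detect_modules, eigenmetabolites,
                       hub_ranking, metabolite_significance,
                       module_significance, module_subgraph,
                       paper_shaped_fixture, preprocess, suggest_annotations,
                       tom_summary, topological_overlap)
from metabonet.io import PreprocessConfig

table, traits, truth = paper_shaped_fixture()
table = preprocess(table, PreprocessConfig(transform="log2"))
tom = topological_overlap(
    adjacency(correlation_matrix(table), NetworkConfig(power=4)))
labels = detect_modules(table, tom, DetectionConfig(min_cluster_size=6))

gs = metabolite_significance(table, traits.vector("diet"), "diet")
module = module_significance(gs, labels).idxmax()
summary = tom_summary(tom, labels, module)
print(f"module: {module}; within-module TOM "
      f"{summary['min']:.4f}..{summary['max']:.4f}, "
      f"mean {summary['mean']:.4f} +/- {summary['sd']:.4f}")

graph = module_subgraph(tom, labels, module, threshold=0.13,
                        meta=table.meta)
print(f"graph: {graph.number_of_nodes()} nodes, "
      f"{graph.number_of_edges()} edges above TOM 0.13")

ranked = hub_ranking(graph, tom)
print("\ntop 5 by weighted degree:")
print(ranked.head(5)[["feature_id", "weighted_degree", "degree",
                      "is_hub"]].to_string(index=False))

suggestions = suggest_annotations(graph, k=3)
shown = 0
for unknown, lst in suggestions.items():
    if lst and shown < 3:
        nbrs = ", ".join(f"{n} (TOM {w:.3f})" for n, w in lst)
        print(f"unknown {unknown}: candidate identities from {nbrs}")
        shown += 1
# The hub is the most connected metabolite of the module; unknown features
# inherit candidate annotations from the identified features they connect
# to most strongly.
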