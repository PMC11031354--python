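"""Hierarchical and synonym propagation of cell-type annotations.

Builds a miniature curated relationship table, then shows how a single
raw annotation expands into its multi-label closure: child labels reach
every ancestor, and synonym labels imply each other.
"""

from ontoannot import CellTypeGraph, LabelMatrix, propagate_labels, propagate_label_matrix

graph = CellTypeGraph()
graph.add_edge("ciliated epithelial cell", "ciliated cell", "parent")
graph.add_edge("ciliated epithelial cell", "epithelial cell", "parent")
graph.add_edge("vein endothelial cell", "blood vessel endothelial cell", "synonym")

for raw in ("ciliated epithelial cell", "vein endothelial cell", "T cell"):
    closure = propagate_labels({raw}, graph)
    print(f"{raw!r} -> {sorted(closure)}")

types = sorted(graph.nodes)
cells = ["cell_1", "cell_2"]
raw = LabelMatrix.from_labels(cells, ["ciliated epithelial cell", "vein endothelial cell"], types)
corrected = propagate_label_matrix(raw, graph)
print("\nraw row sums:", raw.values.sum(axis=1).tolist(),
      "-> propagated row sums:", corrected.values.sum(axis=1).tolist())
# Each row gained the ancestors/synonyms of its label: the multi-label
# gold standard now credits a model that calls either name or the parent.
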