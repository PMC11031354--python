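"""Generate a synthetic multi-dataset corpus with annotation mismatch.

Each dataset annotates with one style: specific leaf labels, broad
parent labels, or synonym alias labels.  The printed crosstab shows how
the same true cell type is recorded differently across datasets — the
inconsistency the ontology correction later repairs.
"""

import pandas as pd

from ontoannot import SimulationConfig, simulate_corpus

config = SimulationConfig(n_datasets=4, cells_per_dataset=300, n_genes=100,
                          n_leaf_types=6, n_parent_types=2, n_synonym_pairs=1,
                          markers_per_type=5, seed=0)
corpus = simulate_corpus(config)

print(f"{corpus.total_cells} cells, {len(corpus.graph.nodes)} cell-type labels")
print("dataset annotation styles:", corpus.styles)

df = pd.DataFrame({
    "dataset": [d for d in corpus.dataset_ids for _ in corpus.cell_ids[d]],
    "true": [l for d in corpus.dataset_ids for l in corpus.true_labels[d]],
    "observed": corpus.observed_label_list(),
})
sub = df[df.true == "leaf_00"]
print("\nobserved label of true 'leaf_00' cells, by dataset:")
print(sub.groupby(["dataset", "observed"]).size())
# Parent-style datasets record these cells as their parent type and
# synonym-style datasets as the alias label, so the raw gold standard
# disagrees across datasets about identical cells.
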