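"""Synthetic multi-dataset scRNA-seq corpora with annotation mismatch.

The generator emulates the two labeling inconsistencies that plague
public single-cell corpora: *hierarchical error* (some datasets annotate
at a broad parent level, others at the specific leaf level) and
*synonym error* (the same biological type recorded under two different
label strings), together with dataset batch effects that make
cross-dataset generalization non-trivial.

Expression model: gene counts are negative binomial with mean
``base_mean · exp(batch_offset) · (1 + marker_effect · marker)`` where
batch offsets are Normal(0, batch_sd) per dataset × gene and each type's
marker set is hierarchical — a parent's markers are shared by all its
leaves, so parent-level signal exists and parent-level annotation is
learnable.  A synonym pair is one biological population carrying two
label strings; the alias leaf shares its primary leaf's parent and
markers and owns no cells of its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import floor
from pathlib import Path

import numpy as np
import pandas as pd

from ontoannot.corpus import (
    ChunkStore,
    chunk_cells,
    normalize_log1p_cp10k,
    write_expression_mtx,
)
from ontoannot.ontology import PARENT, SYNONYM, CellTypeGraph, LabelMatrix

logger = logging.getLogger(__name__)

LEAF_STYLE = "leaf"
PARENT_STYLE = "parent"
SYNONYM_STYLE = "synonym"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic corpus.

    Defaults are the desk-scale reference configuration: 8 datasets of
    1,500 cells over 300 genes, an ontology of 12 leaf labels under 4
    parents with 2 synonym pairs, half the datasets annotating at parent
    level and half of the remaining leaf-level datasets using the
    synonym alias labels.
    """

    n_datasets: int = 8
    cells_per_dataset: int = 1500
    n_genes: int = 300
    n_leaf_types: int = 12
    n_parent_types: int = 4
    n_synonym_pairs: int = 2
    markers_per_type: int = 10
    marker_effect: float = 3.0      # relative mean uplift on marker genes
    base_mean: float = 0.5          # NB mean for non-marker genes
    dispersion: float = 2.0         # NB shape θ; var = μ + μ²/θ
    granularity_fraction: float = 0.5   # fraction of datasets annotating at parent level
    synonym_datasets: tuple[str, ...] | None = None  # None → half of the leaf-level datasets
    batch_sd: float = 0.6           # sd of per-dataset × gene log-scale offsets
    seed: int = 0

    def __post_init__(self):
        if min(self.n_datasets, self.cells_per_dataset, self.n_genes,
               self.n_leaf_types, self.n_parent_types, self.markers_per_type) < 1:
            raise ValueError("all counts must be positive")
        if self.n_leaf_types < self.n_parent_types:
            raise ValueError("need at least as many leaf types as parents")
        if self.n_synonym_pairs < 0 or 2 * self.n_synonym_pairs > self.n_leaf_types:
            raise ValueError("more synonym pairs than leaf labels can support")
        if not (0.0 <= self.granularity_fraction <= 1.0):
            raise ValueError("granularity_fraction must be in [0, 1]")
        if self.dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("base_mean and dispersion must be positive")
        n_marked = self.n_parent_types + self.n_leaf_types - self.n_synonym_pairs
        if n_marked * self.markers_per_type > self.n_genes:
            raise ValueError("not enough genes for disjoint marker sets")


@dataclass
class SimulatedCorpus:
    """A generated corpus plus its bookkeeping (truth and distortion map)."""

    config: SimulationConfig
    graph: CellTypeGraph
    gene_ids: list[str]
    dataset_ids: list[str]
    matrices: dict[str, np.ndarray]          # dataset → cells × genes counts
    cell_ids: dict[str, list[str]]
    true_labels: dict[str, list[str]]        # canonical leaf per cell
    leaf_parent: dict[str, str]              # leaf label → parent label
    alias_of: dict[str, str]                 # alias leaf → canonical leaf
    observed_labels: dict[str, list[str]] | None = None
    styles: dict[str, str] | None = None     # dataset → annotation style

    @property
    def total_cells(self) -> int:
        return sum(m.shape[0] for m in self.matrices.values())

    def all_cell_ids(self) -> list[str]:
        return [c for d in self.dataset_ids for c in self.cell_ids[d]]

    def observed_label_list(self) -> list[str]:
        if self.observed_labels is None:
            raise ValueError("corpus has no observed labels; apply distortion first")
        return [l for d in self.dataset_ids for l in self.observed_labels[d]]

    def label_matrix(self) -> LabelMatrix:
        """Raw single-label gold standard over all graph labels."""
        return LabelMatrix.from_labels(
            self.all_cell_ids(), self.observed_label_list(), sorted(self.graph.nodes)
        )

    def datasets(self):
        """Yield (matrix, cell_ids, dataset_id, observed_labels) per dataset."""
        labels = self.observed_labels if self.observed_labels is not None else self.true_labels
        for d in self.dataset_ids:
            yield self.matrices[d], self.cell_ids[d], d, labels[d]


def _round_half_up(x: float) -> int:
    return int(floor(x + 0.5))


def simulate_ontology(config: SimulationConfig):
    """Build the generating cell-type graph.

    Leaves ``leaf_00..`` are assigned round-robin to parents
    ``parent_0..``.  The last ``n_synonym_pairs`` leaf labels act as
    synonym aliases: alias k is paired with canonical leaf k, shares its
    parent, and carries both directed synonym edges.

    Returns ``(graph, leaf_parent, alias_of)``.
    """
    n_primary = config.n_leaf_types - config.n_synonym_pairs
    parents = [f"parent_{i}" for i in range(config.n_parent_types)]
    primary = [f"leaf_{i:02d}" for i in range(n_primary)]
    aliases = [f"leaf_{n_primary + k:02d}" for k in range(config.n_synonym_pairs)]

    graph = CellTypeGraph()
    leaf_parent: dict[str, str] = {}
    alias_of: dict[str, str] = {}
    for p in parents:
        graph.add_node(p)
    for i, leaf in enumerate(primary):
        leaf_parent[leaf] = parents[i % config.n_parent_types]
        graph.add_edge(leaf, leaf_parent[leaf], PARENT)
    for k, alias in enumerate(aliases):
        canon = primary[k]
        alias_of[alias] = canon
        leaf_parent[alias] = leaf_parent[canon]
        graph.add_edge(alias, leaf_parent[alias], PARENT)
        graph.add_edge(canon, alias, SYNONYM)
    graph.validate()
    return graph, leaf_parent, alias_of


def simulate_expression(config: SimulationConfig) -> SimulatedCorpus:
    """Draw the corpus: cells, counts, batch offsets, true leaf labels."""
    graph, leaf_parent, alias_of = simulate_ontology(config)
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{j:04d}" for j in range(config.n_genes)]
    dataset_ids = [f"ds{d:02d}" for d in range(config.n_datasets)]

    primary = sorted(set(leaf_parent) - set(alias_of))
    parents = sorted({leaf_parent[l] for l in primary})
    marked = parents + primary  # aliases share their canonical leaf's markers
    markers: dict[str, np.ndarray] = {}
    gene_pool = rng.permutation(config.n_genes)
    for i, t in enumerate(marked):
        markers[t] = gene_pool[i * config.markers_per_type:(i + 1) * config.markers_per_type]

    matrices, cell_ids, true_labels = {}, {}, {}
    theta = config.dispersion
    for d in dataset_ids:
        offsets = rng.normal(0.0, config.batch_sd, size=config.n_genes)
        leaves = rng.choice(primary, size=config.cells_per_dataset)
        uplift = np.ones((config.cells_per_dataset, config.n_genes))
        for leaf in primary:
            sel = leaves == leaf
            if not sel.any():
                continue
            marked_genes = np.concatenate([markers[leaf], markers[leaf_parent[leaf]]])
            uplift[np.ix_(sel, marked_genes)] = 1.0 + config.marker_effect
        mu = config.base_mean * np.exp(offsets)[None, :] * uplift
        counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(np.float32)
        matrices[d] = counts
        cell_ids[d] = [f"{d}:c{i:05d}" for i in range(config.cells_per_dataset)]
        true_labels[d] = [str(l) for l in leaves]

    return SimulatedCorpus(
        config=config,
        graph=graph,
        gene_ids=gene_ids,
        dataset_ids=dataset_ids,
        matrices=matrices,
        cell_ids=cell_ids,
        true_labels=true_labels,
        leaf_parent=leaf_parent,
        alias_of=alias_of,
    )


def apply_annotation_distortion(corpus: SimulatedCorpus, config: SimulationConfig) -> SimulatedCorpus:
    """Assign each dataset an annotation style and distort its labels.

    ``round(granularity_fraction · n_datasets)`` randomly chosen datasets
    annotate every cell at its parent type; of the remaining leaf-level
    datasets, the configured synonym datasets (default: a random half)
    use the alias label for leaves that have one.  Everywhere else the
    observed label is the true leaf.  Styles are drawn from a stream
    derived from the corpus seed, so the full generation is reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    n_gran = _round_half_up(config.granularity_fraction * config.n_datasets)
    order = [corpus.dataset_ids[i] for i in rng.permutation(config.n_datasets)]
    gran = set(order[:n_gran])
    leaf_level = [d for d in order if d not in gran]
    if config.synonym_datasets is not None:
        syn = set(config.synonym_datasets)
        if not syn <= set(corpus.dataset_ids) or syn & gran:
            raise ValueError("synonym_datasets must be leaf-level dataset ids")
    else:
        syn = set(leaf_level[: len(leaf_level) // 2])

    canon_alias = {c: a for a, c in corpus.alias_of.items()}
    styles, observed = {}, {}
    for d in corpus.dataset_ids:
        if d in gran:
            styles[d] = PARENT_STYLE
            observed[d] = [corpus.leaf_parent[l] for l in corpus.true_labels[d]]
        elif d in syn:
            styles[d] = SYNONYM_STYLE
            observed[d] = [canon_alias.get(l, l) for l in corpus.true_labels[d]]
        else:
            styles[d] = LEAF_STYLE
            observed[d] = list(corpus.true_labels[d])
    corpus.styles = styles
    corpus.observed_labels = observed
    logger.info(
        "annotation styles: %d parent-level, %d synonym, %d leaf-level",
        len(gran), len(syn), len(corpus.dataset_ids) - len(gran) - len(syn),
    )
    return corpus


def simulate_corpus(config: SimulationConfig | None = None) -> SimulatedCorpus:
    """Generate a fully annotated corpus (expression + distorted labels)."""
    config = config or SimulationConfig()
    return apply_annotation_distortion(simulate_expression(config), config)


def build_chunk_store(
    corpus: SimulatedCorpus,
    root,
    chunk_size: int = 100,
    normalize: bool = False,
) -> ChunkStore:
    """Write the corpus into a chunk store, optionally log1p-CP10K normalized."""
    store = ChunkStore.create(root)

    def stream():
        for matrix, cids, d, labels in corpus.datasets():
            if normalize:
                matrix = normalize_log1p_cp10k(matrix)
            yield matrix, cids, d, labels

    return chunk_cells(stream(), store, chunk_size=chunk_size)


def write_corpus(corpus: SimulatedCorpus, out_dir) -> None:
    """Write MTX datasets, the edge table and a truth table to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = corpus.observed_labels or corpus.true_labels
    for d in corpus.dataset_ids:
        meta = pd.DataFrame(
            {"cell_id": corpus.cell_ids[d], "dataset_id": d, "cell_type": labels[d]}
        )
        write_expression_mtx(out / d, corpus.matrices[d], corpus.gene_ids,
                             corpus.cell_ids[d], meta)
    edges = pd.DataFrame(
        [(u, v, k) for u, v, k in corpus.graph.edges if k == PARENT or u < v],
        columns=["child", "parent", "relation"],
    )
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    truth = pd.DataFrame(
        {
            "cell_id": corpus.all_cell_ids(),
            "dataset_id": [d for d in corpus.dataset_ids for _ in corpus.cell_ids[d]],
            "true_type": [l for d in corpus.dataset_ids for l in corpus.true_labels[d]],
            "observed_type": corpus.observed_label_list() if corpus.observed_labels else
                             [l for d in corpus.dataset_ids for l in corpus.true_labels[d]],
            "style": [corpus.styles[d] if corpus.styles else LEAF_STYLE
                      for d in corpus.dataset_ids for _ in corpus.cell_ids[d]],
        }
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
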