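import numpy as np
import pytest

from ontoannot import (
    ModelConfig,
    SimulationConfig,
    simulate_corpus,
)
from ontoannot.simulate import build_chunk_store


def small_sim_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A miniature corpus: 4 datasets × 120 cells, 60 genes, 6 leaves."""
    kwargs = dict(
        n_datasets=4,
        cells_per_dataset=120,
        n_genes=60,
        n_leaf_types=6,
        n_parent_types=2,
        n_synonym_pairs=1,
        markers_per_type=4,
        marker_effect=3.0,
        batch_sd=0.4,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def small_model_config(n_types: int, seed: int = 7, **overrides) -> ModelConfig:
    kwargs = dict(
        input_dim=60,
        output_dim=n_types,
        hidden_widths=(32, 16),
        learning_rate=1e-3,
        epochs=6,
        seed=seed,
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


@pytest.fixture(scope="session")
def small_corpus():
    return simulate_corpus(small_sim_config())


@pytest.fixture(scope="session")
def small_store(small_corpus, tmp_path_factory):
    root = tmp_path_factory.mktemp("store")
    return build_chunk_store(small_corpus, root, chunk_size=40, normalize=True)


def random_graph_edges(rng: np.random.Generator, n_nodes: int, n_edges: int):
    """Random mixed parent/synonym edge list over labeled nodes."""
    nodes = [f"t{i}" for i in range(n_nodes)]
    edges = []
    for _ in range(n_edges):
        a, b = rng.choice(n_nodes, size=2, replace=False)
        kind = "synonym" if rng.random() < 0.3 else "parent"
        edges.append((nodes[a], nodes[b], kind))
    return nodes, edges


def brute_force_closure(start: set[str], edges) -> set[str]:
    """Independent reachability oracle: relax directed edges to fixpoint.

    Parent edges are followed child→parent; synonym edges both ways.
    """
    directed = []
    for a, b, kind in edges:
        directed.append((a, b))
        if kind == "synonym":
            directed.append((b, a))
    out = set(start)
    changed = True
    while changed:
        changed = False
        for a, b in directed:
            if a in out and b not in out:
                out.add(b)
                changed = True
    return out
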