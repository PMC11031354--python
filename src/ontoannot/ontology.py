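"""Cell-type graph parsing and annotation propagation.

The gold-standard annotation of a cell is corrected by propagating it
upward through child→parent (is-a) relations and across synonym links,
turning a single-label annotation into a multi-label one.  The substrate
is a small directed graph built from a hand-curated two-relation edge
table; synonym edges are stored in both directions so that plain
reachability implements both kinds of propagation at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PARENT = "parent"
SYNONYM = "synonym"
_RELATIONS = (PARENT, SYNONYM)


class EdgeTableError(ValueError):
    """Malformed cell-type relationship table."""


@dataclass
class CellTypeGraph:
    """Directed graph of cell-type labels with parent and synonym edges.

    Parent edges point child→parent.  Synonym edges are symmetric: adding
    (a, b, synonym) implies (b, a, synonym).  Self-loops are rejected.
    The annotation closure of a label is the set of nodes reachable from
    it along edges of either kind.
    """

    _g: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        return [(u, v, d["kind"]) for u, v, d in self._g.edges(data=True)]

    def n_edges(self, kind: str | None = None) -> int:
        if kind is None:
            return self._g.number_of_edges()
        return sum(1 for _, _, k in self.edges if k == kind)

    def add_node(self, label: str) -> None:
        self._g.add_node(label)

    def add_edge(self, source: str, target: str, kind: str) -> None:
        if kind not in _RELATIONS:
            raise EdgeTableError(f"unknown relation kind {kind!r}")
        if source == target:
            raise EdgeTableError(f"self-loop edge on {source!r}")
        self._g.add_edge(source, target, kind=kind)
        if kind == SYNONYM:
            self._g.add_edge(target, source, kind=SYNONYM)

    def has_node(self, label: str) -> bool:
        return self._g.has_node(label)

    def closure(self, label: str) -> set[str]:
        """All labels reachable from ``label`` (including itself)."""
        if not self._g.has_node(label):
            return {label}
        return {label} | nx.descendants(self._g, label)

    def validate(self) -> None:
        """Check structural invariants; raise EdgeTableError on violation."""
        for u, v, kind in self.edges:
            if u == v:
                raise EdgeTableError(f"self-loop on {u!r}")
            if kind == SYNONYM and not (
                self._g.has_edge(v, u) and self._g[v][u]["kind"] == SYNONYM
            ):
                raise EdgeTableError(f"synonym edge {u!r}→{v!r} not symmetric")
        parent_only = nx.DiGraph(
            (u, v) for u, v, k in self.edges if k == PARENT
        )
        if parent_only.number_of_edges() and not nx.is_directed_acyclic_graph(parent_only):
            logger.warning("parent edges contain a cycle; reachability still terminates")


_DEFAULT_DIALECT = {"child": "child", "parent": "parent", "relation": "relation"}


def load_edge_table(path, dialect: dict[str, str] | None = None) -> CellTypeGraph:
    """Parse a curated TSV of child→parent and synonym pairs into a graph.

    Parameters
    ----------
    path
        TSV with a header row; required columns ``child``, ``parent``,
        ``relation`` (relation ∈ {parent, synonym}).
    dialect
        Optional mapping from the canonical column names to the names
        used in the file, e.g. ``{"child": "term", "parent": "ancestor"}``.

    Labels are whitespace-trimmed; duplicate rows collapse to one edge;
    synonym rows yield both directed edges.  Rows whose two labels are
    equal after trimming are rejected with their row number.
    """
    dialect = {**_DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for canon in ("child", "parent", "relation"):
        col = dialect[canon]
        if col not in df.columns:
            raise EdgeTableError(
                f"edge table {path} is missing required column {col!r}"
            )
    graph = CellTypeGraph()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        child = getattr(row, dialect["child"]).strip()
        parent = getattr(row, dialect["parent"]).strip()
        relation = getattr(row, dialect["relation"]).strip().lower()
        if relation not in _RELATIONS:
            raise EdgeTableError(
                f"row {i}: relation must be one of {_RELATIONS}, got {relation!r}"
            )
        if not child or not parent:
            raise EdgeTableError(f"row {i}: empty label")
        if child == parent:
            raise EdgeTableError(f"row {i}: self-loop on {child!r}")
        graph.add_edge(child, parent, relation)
    graph.validate()
    logger.info(
        "edge table %s: %d nodes, %d parent edges, %d synonym edges (directed)",
        path, len(graph.nodes), graph.n_edges(PARENT), graph.n_edges(SYNONYM),
    )
    return graph


def propagate_labels(raw: set[str], graph: CellTypeGraph) -> set[str]:
    """Annotation closure of a raw label set.

    Returns every label reachable from any raw label by following parent
    edges upward and synonym edges in either direction, to fixpoint.  A
    superset of ``raw``; idempotent.  Labels absent from the graph pass
    through unchanged (the curated table cannot be assumed complete).
    """
    out: set[str] = set()
    off_graph = 0
    for label in raw:
        if not graph.has_node(label):
            off_graph += 1
        out |= graph.closure(label)
    if off_graph:
        logger.debug("%d off-graph label(s) propagated to themselves", off_graph)
    return out


@dataclass
class LabelMatrix:
    """Cells × types binary gold-standard matrix.

    ``mode`` is ``"raw"`` (exactly one 1 per row) or ``"propagated"``
    (row support is the annotation closure of the raw label, restricted
    to ``type_ids``).
    """

    cell_ids: list[str]
    type_ids: list[str]
    values: np.ndarray  # (n_cells, n_types) uint8
    mode: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.cell_ids), len(self.type_ids)):
            raise ValueError(
                f"label matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.type_ids)} types"
            )
        if self.mode not in ("raw", "propagated"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_labels(
        cls, cell_ids: list[str], labels: list[str], type_ids: list[str]
    ) -> "LabelMatrix":
        """Build a single-label (raw) matrix from one label per cell."""
        if len(cell_ids) != len(labels):
            raise ValueError("cell_ids and labels length mismatch")
        col = {t: j for j, t in enumerate(type_ids)}
        values = np.zeros((len(cell_ids), len(type_ids)), dtype=np.uint8)
        missing = 0
        for i, lab in enumerate(labels):
            j = col.get(lab)
            if j is None:
                missing += 1
            else:
                values[i, j] = 1
        if missing:
            logger.warning("%d cell label(s) not in type_ids; rows left empty", missing)
        return cls(list(cell_ids), list(type_ids), values, mode="raw")

    def row_support(self, i: int) -> set[str]:
        return {self.type_ids[j] for j in np.flatnonzero(self.values[i])}


def propagate_label_matrix(raw: LabelMatrix, graph: CellTypeGraph) -> LabelMatrix:
    """Propagate every row of a raw label matrix through the graph.

    Each row's support becomes the closure of its raw label(s), restricted
    to ``type_ids``; labels produced by propagation but absent from the
    column vocabulary are counted and logged.  Output mode is "propagated".
    """
    if raw.mode != "raw":
        raise ValueError("propagate_label_matrix expects a raw-mode matrix")
    col = {t: j for j, t in enumerate(raw.type_ids)}
    # closure per distinct column index is enough: raw rows are one-hot
    closure_cols: dict[int, list[int]] = {}
    dropped: set[str] = set()
    for t, j in col.items():
        closed = propagate_labels({t}, graph)
        closure_cols[j] = [col[u] for u in closed if u in col]
        dropped |= {u for u in closed if u not in col}
    values = np.zeros_like(raw.values)
    for i in range(values.shape[0]):
        for j in np.flatnonzero(raw.values[i]):
            values[i, closure_cols[int(j)]] = 1
    if dropped:
        logger.info(
            "%d propagated label(s) absent from type_ids were dropped: %s",
            len(dropped), sorted(dropped)[:10],
        )
    return LabelMatrix(raw.cell_ids, raw.type_ids, values, mode="propagated")
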