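"""Expression I/O, gene alignment, chunked on-disk corpus, and splits.

Large corpora are never held in memory: each dataset is cut into
fixed-size blocks of cells ("chunks", default 100 — one training batch
per chunk) stored as one portable ``.npz`` file each, indexed by a JSON
manifest.  Train/test splits are drawn at the level of whole datasets so
that no dataset contributes cells to both sides of an evaluation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

REQUIRED_METADATA = ("cell_id", "dataset_id", "cell_type")


class FormatError(ValueError):
    """Input files do not match the expected layout."""


# ---------------------------------------------------------------------------
# gene vocabulary

def read_gene_vocab(path) -> list[str]:
    """Read an ordered gene vocabulary (one identifier per line, TSV)."""
    genes = [ln.split("\t")[0].strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(set(genes)) != len(genes):
        raise FormatError(f"gene vocabulary {path} contains duplicates")
    return genes


def write_gene_vocab(genes: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


# ---------------------------------------------------------------------------
# expression loading

def load_expression(path, format: str = "mtx"):
    """Load one dataset's expression matrix plus per-cell metadata.

    ``mtx``: *path* is a directory holding ``matrix.mtx`` (MatrixMarket
    coordinate, genes × cells), ``genes.tsv``, ``barcodes.tsv`` and
    ``metadata.tsv`` (columns ``cell_id``, ``dataset_id``, ``cell_type``).
    ``hdf5``: *path* is a file with datasets ``/X`` (genes × cells),
    ``/var/gene_ids``, ``/obs/cell_id``, ``/obs/dataset_id``,
    ``/obs/cell_type``.

    Returns ``(matrix, gene_ids, cell_ids, metadata)`` with *matrix*
    oriented cells × genes (dense float32) for downstream alignment.
    """
    if format == "mtx":
        d = Path(path)
        mat = scipy.io.mmread(d / "matrix.mtx")  # genes x cells
        gene_ids = read_gene_vocab(d / "genes.tsv")
        cell_ids = [ln.strip() for ln in (d / "barcodes.tsv").read_text().splitlines() if ln.strip()]
        metadata = pd.read_csv(d / "metadata.tsv", sep="\t", dtype=str)
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            mat = f["/X"][...]
            gene_ids = [g.decode() if isinstance(g, bytes) else str(g) for g in f["/var/gene_ids"][...]]
            obs = {}
            for c in REQUIRED_METADATA:
                obs[c] = [v.decode() if isinstance(v, bytes) else str(v) for v in f[f"/obs/{c}"][...]]
            cell_ids = obs["cell_id"]
            metadata = pd.DataFrame(obs)
    else:
        raise ValueError(f"unknown format {format!r}")

    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float32)
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix is {mat.shape} but sidecars describe "
            f"{len(gene_ids)} genes × {len(cell_ids)} cells"
        )
    for c in REQUIRED_METADATA:
        if c not in metadata.columns:
            raise FormatError(f"metadata is missing required column {c!r}")
    if len(metadata) != len(cell_ids):
        raise FormatError(
            f"metadata has {len(metadata)} rows for {len(cell_ids)} cells"
        )
    return mat.T.copy(), gene_ids, cell_ids, metadata


def write_expression_mtx(path, matrix, gene_ids, cell_ids, metadata: pd.DataFrame) -> None:
    """Write a cells × genes matrix as an MTX directory (genes × cells on disk)."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), scipy.sparse.coo_matrix(np.asarray(matrix).T))
    write_gene_vocab(gene_ids, d / "genes.tsv")
    Path(d / "barcodes.tsv").write_text("\n".join(cell_ids) + "\n")
    metadata.to_csv(d / "metadata.tsv", sep="\t", index=False)


def align_genes(matrix, gene_ids: Sequence[str], vocab: Sequence[str]):
    """Project a cells × genes matrix onto a fixed gene vocabulary.

    Columns are reordered to vocabulary order; vocabulary genes absent
    from the dataset are zero-filled; dataset genes outside the
    vocabulary are dropped.  Values of shared genes are unchanged.
    """
    idx = {g: j for j, g in enumerate(gene_ids)}
    shared = [g for g in vocab if g in idx]
    if not shared:
        raise FormatError("dataset shares no genes with the vocabulary")
    matrix = np.asarray(matrix)
    out = np.zeros((matrix.shape[0], len(vocab)), dtype=matrix.dtype)
    for j, g in enumerate(vocab):
        if g in idx:
            out[:, j] = matrix[:, idx[g]]
    n_missing = len(vocab) - len(shared)
    n_dropped = len(gene_ids) - len(shared)
    if n_missing or n_dropped:
        logger.info(
            "gene alignment: %d vocabulary genes zero-filled, %d dataset genes dropped",
            n_missing, n_dropped,
        )
    return out


def normalize_log1p_cp10k(matrix: np.ndarray) -> np.ndarray:
    """Depth-normalize each cell to 10,000 counts and apply log1p."""
    matrix = np.asarray(matrix, dtype=np.float32)
    depth = matrix.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    return np.log1p(matrix / depth * 1e4)


# ---------------------------------------------------------------------------
# chunk store

@dataclass
class ExpressionChunk:
    """One fixed-size block of cells from a single dataset."""

    matrix: np.ndarray          # (n_cells, G) float32, aligned to the vocabulary
    cell_ids: list[str]
    dataset_id: str
    raw_labels: list[str]       # one observed label per cell

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        n = self.matrix.shape[0]
        if not (len(self.cell_ids) == len(self.raw_labels) == n):
            raise ValueError("chunk row count mismatch")
        if not np.all(np.isfinite(self.matrix)) or np.any(self.matrix < 0):
            raise ValueError("chunk values must be finite and non-negative")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


class ChunkStore:
    """On-disk corpus of expression chunks with a JSON manifest.

    Layout: ``root/manifest.json`` plus one ``chunk_#####.npz`` per chunk
    (arrays ``matrix``, ``cell_ids``, ``raw_labels``; scalar
    ``dataset_id``).  Each dataset's chunks occupy contiguous manifest
    entries, and manifest cell totals always equal the stored cells.
    """

    def __init__(self, root):
        self.root = Path(root)
        self.manifest: list[dict] = []
        mpath = self.root / "manifest.json"
        if mpath.exists():
            self.manifest = json.loads(mpath.read_text())["chunks"]

    @classmethod
    def create(cls, root) -> "ChunkStore":
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        store = cls(root)
        store.manifest = []
        store._save_manifest()
        return store

    def _save_manifest(self) -> None:
        payload = {"total_cells": self.total_cells, "chunks": self.manifest}
        (self.root / "manifest.json").write_text(json.dumps(payload, indent=1))

    @property
    def total_cells(self) -> int:
        return sum(e["n_cells"] for e in self.manifest)

    @property
    def dataset_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.manifest:
            seen.setdefault(e["dataset_id"])
        return list(seen)

    def __len__(self) -> int:
        return len(self.manifest)

    def append(self, chunk: ExpressionChunk) -> None:
        fname = f"chunk_{len(self.manifest):05d}.npz"
        np.savez(
            self.root / fname,
            matrix=chunk.matrix,
            cell_ids=np.array(chunk.cell_ids, dtype=str),
            raw_labels=np.array(chunk.raw_labels, dtype=str),
            dataset_id=np.array(chunk.dataset_id, dtype=str),
        )
        self.manifest.append(
            {"file": fname, "dataset_id": chunk.dataset_id, "n_cells": chunk.n_cells}
        )
        self._save_manifest()

    def load(self, index: int) -> ExpressionChunk:
        entry = self.manifest[index]
        with np.load(self.root / entry["file"]) as z:
            return ExpressionChunk(
                matrix=z["matrix"],
                cell_ids=[str(c) for c in z["cell_ids"]],
                dataset_id=str(z["dataset_id"]),
                raw_labels=[str(l) for l in z["raw_labels"]],
            )

    def indices_for(self, dataset_ids: Iterable[str] | None = None) -> list[int]:
        if dataset_ids is None:
            return list(range(len(self.manifest)))
        wanted = set(dataset_ids)
        return [i for i, e in enumerate(self.manifest) if e["dataset_id"] in wanted]

    def iter_chunks(self, indices: Sequence[int] | None = None) -> Iterator[ExpressionChunk]:
        for i in indices if indices is not None else range(len(self.manifest)):
            yield self.load(i)


def chunk_cells(
    datasets: Iterable[tuple[np.ndarray, Sequence[str], str, Sequence[str]]],
    store: ChunkStore,
    chunk_size: int = 100,
) -> ChunkStore:
    """Cut each dataset into blocks of ``chunk_size`` cells and store them.

    ``datasets`` yields ``(matrix, cell_ids, dataset_id, raw_labels)``
    with matrices already aligned to a common vocabulary.  Every cell
    lands in exactly one chunk; all chunks except possibly the last per
    dataset are full.
    """
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    for matrix, cell_ids, dataset_id, raw_labels in datasets:
        n = matrix.shape[0]
        for start in range(0, n, chunk_size):
            stop = min(start + chunk_size, n)
            store.append(
                ExpressionChunk(
                    matrix=matrix[start:stop],
                    cell_ids=list(cell_ids[start:stop]),
                    dataset_id=dataset_id,
                    raw_labels=list(raw_labels[start:stop]),
                )
            )
    return store


# ---------------------------------------------------------------------------
# splits

@dataclass
class DatasetSplit:
    """Disjoint, exhaustive train/test partition of dataset identifiers."""

    train_datasets: set[str]
    test_datasets: set[str]
    seed: int

    def __post_init__(self):
        if self.train_datasets & self.test_datasets:
            raise ValueError("train and test datasets overlap")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_by_dataset(
    dataset_ids: Sequence[str], test_fraction: float = 0.2, seed: int = 0
) -> DatasetSplit:
    """Randomly assign whole datasets to train or test.

    ``round(test_fraction · n)`` datasets (round-half-up, minimum 1) go
    to test; all cells of a dataset stay on one side.  Deterministic for
    a given seed.
    """
    ids = sorted(set(dataset_ids))
    if len(ids) < 2:
        raise ValueError("cross-dataset evaluation needs at least 2 datasets")
    n_test = max(1, _round_half_up(test_fraction * len(ids)))
    if n_test >= len(ids):
        raise ValueError("test fraction leaves no training datasets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    test = {ids[i] for i in perm[:n_test]}
    return DatasetSplit(train_datasets=set(ids) - test, test_datasets=test, seed=seed)


def validation_holdout(
    chunk_indices: Sequence[int], fraction: float = 0.1, seed: int = 0
) -> tuple[list[int], list[int]]:
    """Hold out a random fraction of training chunks for validation.

    Returns ``(train_indices, validation_indices)``, disjoint and
    exhaustive, deterministic for a given seed.  With ``fraction == 0``
    the validation set is empty and best-epoch selection degenerates to
    the last epoch (a warning is logged).
    """
    idx = list(chunk_indices)
    if fraction == 0:
        logger.warning("empty validation holdout: best-epoch callback degenerates to last epoch")
        return idx, []
    if len(idx) < 2:
        raise ValueError("validation holdout needs at least 2 chunks")
    n_val = max(1, _round_half_up(fraction * len(idx)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(idx))
    val_pos = set(perm[:n_val].tolist())
    train = [idx[i] for i in range(len(idx)) if i not in val_pos]
    val = [idx[i] for i in sorted(val_pos)]
    return train, val
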