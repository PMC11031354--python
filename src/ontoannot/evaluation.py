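"""Per-cell-type AUC/AUPRC and cross-dataset cross-validation.

Every cell type is evaluated independently: its score column is ranked
against its own gold column, so a cell annotated to both a child type A
and its parent A′ counts as a positive in both columns, and a prediction
that hits A′ but misses A is correct for A′ and wrong for A.  Types
whose test gold is single-class get no metric (recorded as ineligible),
and the headline median is taken over types evaluated in at least
``min_evaluations`` folds.

"10-fold cross-validation" is Monte-Carlo: ten independent random
dataset-level 80/20 splits, since 20% of the datasets per iteration
cannot form a disjoint 10-way partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from ontoannot.classifier import (
    SIGMOID,
    SOFTMAX,
    ModelConfig,
    TrainedModel,
    predict_scores,
    train,
    train_on_chunks,
)
from ontoannot.corpus import ChunkStore, DatasetSplit, split_by_dataset
from ontoannot.ontology import CellTypeGraph, LabelMatrix, propagate_label_matrix

logger = logging.getLogger(__name__)

RAW = "raw"
CORRECTED = "corrected"


# ---------------------------------------------------------------------------
# metrics

def roc_auc(scores, gold) -> float:
    """Area under the ROC curve for one type's score column.

    Equals the Mann–Whitney statistic (ties counted half).  Returns NaN
    when the gold column is single-class — an undefined metric, recorded
    as ineligible rather than raised.
    """
    gold = np.asarray(gold).astype(int)
    scores = np.asarray(scores, dtype=float)
    if gold.sum() == 0 or gold.sum() == gold.size:
        return float("nan")
    return float(roc_auc_score(gold, scores))


def auprc(scores, gold) -> float:
    """Area under the precision–recall step curve (average precision).

    NaN when the gold column is single-class.
    """
    gold = np.asarray(gold).astype(int)
    scores = np.asarray(scores, dtype=float)
    if gold.sum() == 0 or gold.sum() == gold.size:
        return float("nan")
    return float(average_precision_score(gold, scores))


@dataclass
class TypeMetrics:
    """One cell type's metrics in one cross-validation fold."""

    type_id: str
    fold_id: int
    auc: float      # NaN when undefined
    auprc: float    # NaN when undefined
    n_pos: int
    n_neg: int


def evaluate_fold(
    model: TrainedModel,
    test_chunks,
    gold: LabelMatrix,
    fold_id: int = 0,
    trained_types: set[str] | None = None,
) -> list[TypeMetrics]:
    """Score the test chunks and compute per-type metrics independently.

    Only types appearing (as positives) in the fold's training labels
    are evaluated; pass them as ``trained_types`` (None = all columns).
    Each type's AUC/AUPRC comes from its own score and gold columns.
    """
    test_chunks = list(test_chunks)
    scored = predict_scores(model, test_chunks)
    row_of = {c: i for i, c in enumerate(gold.cell_ids)}
    gold_rows = gold.values[[row_of[c] for c in scored.cell_ids]]
    out = []
    for j, t in enumerate(scored.type_ids):
        if trained_types is not None and t not in trained_types:
            logger.debug("type %s absent from training labels; skipped", t)
            continue
        g = gold_rows[:, j]
        n_pos = int(g.sum())
        n_neg = int(g.size - n_pos)
        s = scored.scores[:, j]
        out.append(
            TypeMetrics(
                type_id=t,
                fold_id=fold_id,
                auc=roc_auc(s, g),
                auprc=auprc(s, g),
                n_pos=n_pos,
                n_neg=n_neg,
            )
        )
    return out


# ---------------------------------------------------------------------------
# report

@dataclass
class EvaluationReport:
    """Per-type, per-fold metrics plus filtered summary medians."""

    metrics: pd.DataFrame  # columns type_id, fold_id, auc, auprc, n_pos, n_neg
    config: dict = field(default_factory=dict)

    def evaluation_counts(self) -> pd.Series:
        """Folds in which each type received a defined AUC."""
        m = self.metrics.dropna(subset=["auc"])
        return m.groupby("type_id")["auc"].size()

    def eligible_types(self, min_evaluations: int | None = None) -> list[str]:
        if min_evaluations is None:
            min_evaluations = self.config.get("min_evaluations", 5)
        counts = self.evaluation_counts()
        return sorted(counts[counts >= min_evaluations].index)

    def median_auc(self, min_evaluations: int | None = None) -> float:
        """Headline statistic: per-type across-fold mean AUC, then the
        median over types meeting the evaluation-count filter."""
        types = self.eligible_types(min_evaluations)
        if not types:
            return float("nan")
        m = self.metrics.dropna(subset=["auc"])
        per_type = m[m.type_id.isin(types)].groupby("type_id")["auc"].mean()
        return float(per_type.median())

    def per_fold_median_auc(self) -> pd.Series:
        """Alternative aggregation order: median over types within each fold."""
        m = self.metrics.dropna(subset=["auc"])
        return m.groupby("fold_id")["auc"].median()


def summarize(report: EvaluationReport, min_evaluations: int | None = None) -> pd.DataFrame:
    """Per-type mean/median AUC and AUPRC across folds, filtered summary.

    Rows are the types passing the min-evaluations filter; the attached
    ``attrs['median_auc']`` carries the headline median.
    """
    if min_evaluations is None:
        min_evaluations = report.config.get("min_evaluations", 5)
    types = report.eligible_types(min_evaluations)
    m = report.metrics.dropna(subset=["auc"])
    m = m[m.type_id.isin(types)]
    if m.empty:
        out = pd.DataFrame(
            columns=["type_id", "n_evaluations", "mean_auc", "median_auc", "mean_auprc", "median_auprc"]
        )
    else:
        out = (
            m.groupby("type_id")
            .agg(
                n_evaluations=("auc", "size"),
                mean_auc=("auc", "mean"),
                median_auc=("auc", "median"),
                mean_auprc=("auprc", "mean"),
                median_auprc=("auprc", "median"),
            )
            .reset_index()
        )
    out.attrs["median_auc"] = report.median_auc(min_evaluations)
    return out


# ---------------------------------------------------------------------------
# cross-validation drivers

def _fold_seed(seed: int, fold: int) -> int:
    return int((seed * 100_003 + 7 * fold + 1) % (2**31 - 1))


def _prepare_gold(labels: LabelMatrix, graph: CellTypeGraph | None, mode: str):
    if mode == RAW:
        return labels, SOFTMAX
    if mode == CORRECTED:
        if graph is None:
            raise ValueError("corrected mode needs a cell-type graph")
        return propagate_label_matrix(labels, graph), SIGMOID
    raise ValueError(f"unknown mode {mode!r}")


def _trained_types(gold: LabelMatrix, cell_ids_in_train: set[str]) -> set[str]:
    rows = [i for i, c in enumerate(gold.cell_ids) if c in cell_ids_in_train]
    pos = gold.values[rows].sum(axis=0)
    return {t for j, t in enumerate(gold.type_ids) if pos[j] > 0}


def _store_cell_map(store: ChunkStore) -> dict[int, list[str]]:
    """Chunk index → cell ids (loaded once per CV run)."""
    return {i: store.load(i).cell_ids for i in range(len(store))}


def cross_dataset_cv(
    store: ChunkStore,
    labels: LabelMatrix,
    graph: CellTypeGraph | None,
    config: ModelConfig,
    n_folds: int = 10,
    test_fraction: float = 0.2,
    min_evaluations: int = 5,
    seed: int = 0,
    mode: str = RAW,
    val_fraction: float = 0.1,
) -> EvaluationReport:
    """Monte-Carlo cross-validation with dataset-level splits.

    Each fold draws a fresh random 80/20 split of whole datasets, trains
    a model from scratch in the requested mode (``raw``: observed
    single labels + softmax; ``corrected``: ontology-propagated labels +
    sigmoid) and evaluates per-type metrics on the held-out datasets.
    """
    gold, activation = _prepare_gold(labels, graph, mode)
    base = replace(config, output_activation=activation)
    cell_map = _store_cell_map(store)
    rows = []
    fold_splits = []
    for fold in range(n_folds):
        fseed = _fold_seed(seed, fold)
        split = split_by_dataset(store.dataset_ids, test_fraction, seed=fseed)
        fold_splits.append(
            {"fold": fold, "train": sorted(split.train_datasets),
             "test": sorted(split.test_datasets)}
        )
        fold_cfg = replace(base, seed=fseed)
        model = train(store, gold, split, fold_cfg, val_fraction=val_fraction)
        train_cells = {
            c for i in store.indices_for(split.train_datasets) for c in cell_map[i]
        }
        test_chunks = store.iter_chunks(store.indices_for(split.test_datasets))
        rows.extend(
            evaluate_fold(model, test_chunks, gold, fold_id=fold,
                          trained_types=_trained_types(gold, train_cells))
        )
    metrics = pd.DataFrame([vars(r) for r in rows])
    return EvaluationReport(
        metrics=metrics,
        config={
            "split": "cross-dataset",
            "mode": mode,
            "n_folds": n_folds,
            "test_fraction": test_fraction,
            "min_evaluations": min_evaluations,
            "seed": seed,
            "folds": fold_splits,
        },
    )


def cross_cell_cv(
    store: ChunkStore,
    labels: LabelMatrix,
    graph: CellTypeGraph | None = None,
    config: ModelConfig | None = None,
    n_folds: int = 10,
    test_fraction: float = 0.2,
    min_evaluations: int = 5,
    seed: int = 0,
    mode: str = RAW,
    val_fraction: float = 0.1,
) -> EvaluationReport:
    """Cross-validation with cell-level (chunk) splits, ignoring datasets.

    Provided to demonstrate how mixing cells of one dataset across the
    train/test boundary inflates measured performance when dataset batch
    effects exist.
    """
    if config is None:
        raise ValueError("config is required")
    gold, activation = _prepare_gold(labels, graph, mode)
    base = replace(config, output_activation=activation)
    cell_map = _store_cell_map(store)
    n_chunks = len(store)
    n_test = max(1, int(np.floor(test_fraction * n_chunks + 0.5)))
    if n_test >= n_chunks:
        raise ValueError("test fraction leaves no training chunks")
    rows = []
    for fold in range(n_folds):
        fseed = _fold_seed(seed, fold)
        rng = np.random.default_rng(fseed)
        perm = rng.permutation(n_chunks)
        test_idx = sorted(perm[:n_test].tolist())
        train_idx = sorted(perm[n_test:].tolist())
        fold_cfg = replace(base, seed=fseed)
        model = train_on_chunks(store, gold, train_idx, fold_cfg, val_fraction=val_fraction)
        train_cells = {c for i in train_idx for c in cell_map[i]}
        test_chunks = store.iter_chunks(test_idx)
        rows.extend(
            evaluate_fold(model, test_chunks, gold, fold_id=fold,
                          trained_types=_trained_types(gold, train_cells))
        )
    metrics = pd.DataFrame([vars(r) for r in rows])
    return EvaluationReport(
        metrics=metrics,
        config={
            "split": "cross-cell",
            "mode": mode,
            "n_folds": n_folds,
            "test_fraction": test_fraction,
            "min_evaluations": min_evaluations,
            "seed": seed,
        },
    )
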