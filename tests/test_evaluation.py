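import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ontoannot.classifier import ModelConfig, TrainedModel
from ontoannot.corpus import ChunkStore, ExpressionChunk
from ontoannot.evaluation import (
    EvaluationReport,
    auprc,
    cross_cell_cv,
    cross_dataset_cv,
    evaluate_fold,
    roc_auc,
    summarize,
)
from ontoannot.ontology import LabelMatrix
from conftest import small_model_config


def pairwise_auc_oracle(scores, gold):
    """O(n²) Mann–Whitney count with half credit for ties."""
    pos = [s for s, g in zip(scores, gold) if g]
    neg = [s for s, g in zip(scores, gold) if not g]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def threshold_sweep_ap_oracle(scores, gold):
    """Average precision by sweeping every unique score threshold (ties grouped)."""
    scores = np.asarray(scores, dtype=float)
    gold = np.asarray(gold, dtype=int)
    total_pos = gold.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        called = scores >= t
        tp = int(gold[called].sum())
        precision = tp / called.sum()
        recall = tp / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.3] * 6, [1, 0, 1, 0, 0, 0]) == 0.5

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            scores = rng.choice([0.1, 0.2, 0.5, 0.7, 0.9], size=n)  # force ties
            gold = rng.integers(0, 2, size=n)
            if 0 < gold.sum() < n:
                assert roc_auc(scores, gold) == pytest.approx(
                    pairwise_auc_oracle(scores, gold), abs=1e-9
                )

    def test_single_class_is_undefined(self):
        assert np.isnan(roc_auc([0.1, 0.9], [1, 1]))
        assert np.isnan(roc_auc([0.1, 0.9], [0, 0]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 64), st.booleans()), min_size=4, max_size=30))
    def test_complement_symmetry(self, pairs):
        # dyadic scores keep 1 - s exact, so ties are preserved under complement
        scores = np.array([s / 64 for s, _ in pairs])
        gold = np.array([g for _, g in pairs], dtype=int)
        if 0 < gold.sum() < gold.size:
            a = roc_auc(scores, gold)
            b = roc_auc(1.0 - scores, gold)
            assert a + b == pytest.approx(1.0, abs=1e-9)


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_prevalence(self):
        assert auprc([0.5] * 5, [1, 1, 0, 0, 0]) == pytest.approx(2 / 5, abs=1e-12)

    def test_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            scores = rng.choice(np.round(rng.uniform(size=6), 3), size=n)
            gold = rng.integers(0, 2, size=n)
            if 0 < gold.sum() < n:
                assert auprc(scores, gold) == pytest.approx(
                    threshold_sweep_ap_oracle(scores, gold), abs=1e-9
                )


def score_injection_model(n_types):
    """Sigmoid model with identity weights: scores == sigmoid(X - 5)."""
    cfg = ModelConfig(input_dim=n_types, output_dim=n_types, hidden_widths=(),
                      output_activation="sigmoid")
    params = [[np.eye(n_types, dtype=np.float32), np.full(n_types, -5.0, dtype=np.float32)]]
    return TrainedModel(cfg, params, 1, pd.DataFrame(), [f"t{j}" for j in range(n_types)])


def chunk_for_scores(scores, dataset="d0"):
    """Expression chunk whose predicted sigmoid scores equal ``scores``."""
    s = np.asarray(scores, dtype=np.float64)
    X = (np.log(s / (1 - s)) + 5.0).astype(np.float32)
    assert (X >= 0).all()
    n = X.shape[0]
    return ExpressionChunk(X, [f"{dataset}:c{i}" for i in range(n)], dataset, ["t0"] * n)


class TestEvaluateFold:
    def test_child_and_parent_columns_scored_independently(self):
        # two cells annotated to both A (t0) and its parent A' (t1); the
        # model hits the parent but misses the child: perfect for A',
        # wrong for A.
        model = score_injection_model(3)
        scores = np.array([
            [0.2, 0.9, 0.5],   # gold {A, A'}
            [0.2, 0.9, 0.5],   # gold {A, A'}
            [0.5, 0.1, 0.9],   # gold {B}
            [0.5, 0.1, 0.9],   # gold {B}
        ])
        gold = LabelMatrix(
            [f"d0:c{i}" for i in range(4)], ["t0", "t1", "t2"],
            np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1], [0, 0, 1]]),
            mode="propagated",
        )
        rows = {m.type_id: m for m in evaluate_fold(model, [chunk_for_scores(scores)], gold)}
        assert rows["t1"].auc == 1.0   # parent ranks perfectly
        assert rows["t0"].auc == 0.0   # child column penalized
        assert rows["t0"].n_pos == 2 and rows["t0"].n_neg == 2

    def test_type_absent_from_training_is_skipped(self):
        model = score_injection_model(2)
        scores = np.array([[0.9, 0.1], [0.1, 0.9]])
        gold = LabelMatrix(["d0:c0", "d0:c1"], ["t0", "t1"], np.eye(2, dtype=int), mode="raw")
        rows = evaluate_fold(model, [chunk_for_scores(scores)], gold, trained_types={"t0"})
        assert [m.type_id for m in rows] == ["t0"]

    def test_single_class_gold_recorded_as_undefined(self):
        model = score_injection_model(2)
        scores = np.array([[0.9, 0.2], [0.8, 0.3]])
        gold = LabelMatrix(["d0:c0", "d0:c1"], ["t0", "t1"],
                           np.array([[1, 0], [1, 0]]), mode="raw")
        rows = {m.type_id: m for m in evaluate_fold(model, [chunk_for_scores(scores)], gold)}
        assert np.isnan(rows["t0"].auc) and np.isnan(rows["t1"].auc)

    def test_per_type_aucs_match_column_extraction_oracle(self):
        rng = np.random.default_rng(7)
        model = score_injection_model(4)
        scores = rng.uniform(0.05, 0.95, size=(30, 4))
        values = rng.integers(0, 2, size=(30, 4))
        values[values.sum(axis=1) == 0, 0] = 1
        gold = LabelMatrix([f"d0:c{i}" for i in range(30)],
                           [f"t{j}" for j in range(4)], values, mode="propagated")
        rows = {m.type_id: m for m in evaluate_fold(model, [chunk_for_scores(scores)], gold)}
        for j in range(4):
            expect = roc_auc(scores[:, j], values[:, j])
            got = rows[f"t{j}"].auc
            assert got == pytest.approx(expect, abs=1e-6)


def report_from(rows):
    return EvaluationReport(
        metrics=pd.DataFrame(rows, columns=["type_id", "fold_id", "auc", "auprc", "n_pos", "n_neg"]),
        config={"min_evaluations": 5},
    )


class TestSummarize:
    def test_single_type_single_fold(self):
        rep = report_from([("tA", 0, 0.8, 0.7, 3, 5)])
        assert rep.median_auc(min_evaluations=1) == 0.8

    def test_min_evaluations_filter(self):
        rows = [("tA", f, 0.9, 0.8, 2, 2) for f in range(6)]
        rows += [("tB", f, 0.2, 0.1, 2, 2) for f in range(3)]
        rep = report_from(rows)
        summary = summarize(rep, min_evaluations=5)
        assert summary.type_id.tolist() == ["tA"]
        assert rep.median_auc(5) == 0.9

    def test_raising_min_evaluations_never_adds_types(self):
        rng = np.random.default_rng(3)
        rows = []
        for t in range(8):
            for f in range(int(rng.integers(1, 10))):
                rows.append((f"t{t}", f, rng.uniform(), rng.uniform(), 2, 2))
        rep = report_from(rows)
        for lo in range(1, 9):
            assert set(rep.eligible_types(lo + 1)) <= set(rep.eligible_types(lo))

    def test_median_matches_sort_and_middle_oracle(self):
        rng = np.random.default_rng(4)
        rows = [(f"t{t}", f, rng.uniform(), rng.uniform(), 2, 2)
                for t in range(7) for f in range(6)]
        rep = report_from(rows)
        per_type = [np.mean([r[2] for r in rows if r[0] == f"t{t}"]) for t in range(7)]
        assert rep.median_auc(5) == pytest.approx(sorted(per_type)[3], abs=1e-12)


class TestCvDrivers:
    def test_single_fold_report(self, small_store, small_corpus):
        raw = small_corpus.label_matrix()
        cfg = small_model_config(len(raw.type_ids), epochs=2)
        rep = cross_dataset_cv(small_store, raw, small_corpus.graph, cfg, n_folds=1, seed=5)
        assert rep.metrics.fold_id.nunique() == 1

    def test_same_seed_gives_identical_reports(self, small_store, small_corpus):
        raw = small_corpus.label_matrix()
        cfg = small_model_config(len(raw.type_ids), epochs=2)
        a = cross_dataset_cv(small_store, raw, small_corpus.graph, cfg, n_folds=2, seed=5)
        b = cross_dataset_cv(small_store, raw, small_corpus.graph, cfg, n_folds=2, seed=5)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)

    def test_cross_cell_works_where_cross_dataset_cannot(self, tmp_path, small_corpus):
        # single-dataset store: dataset-level CV is impossible, cell-level runs
        from ontoannot.corpus import chunk_cells
        d = small_corpus.dataset_ids[0]
        mat = small_corpus.matrices[d]
        labels = small_corpus.observed_labels[d]
        store = chunk_cells(
            [(mat, small_corpus.cell_ids[d], d, labels)],
            ChunkStore.create(tmp_path / "one"), chunk_size=30,
        )
        raw = LabelMatrix.from_labels(
            small_corpus.cell_ids[d], labels, sorted(small_corpus.graph.nodes)
        )
        cfg = small_model_config(len(raw.type_ids), epochs=2)
        with pytest.raises(ValueError, match="2 datasets"):
            cross_dataset_cv(store, raw, small_corpus.graph, cfg, n_folds=1, seed=1)
        rep = cross_cell_cv(store, raw, small_corpus.graph, cfg, n_folds=1, seed=1)
        assert len(rep.metrics) > 0
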