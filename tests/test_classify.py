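import numpy as np
import pandas as pd
import pytest

from hiertype import (
    CellAnnotation,
    ExpressionMatrix,
    RunConfig,
    ValidationError,
    joint_predict,
    posthoc_cluster,
    predict,
    simulate_dataset,
    train_classifier,
)
from hiertype.classify import records_to_frame
from hiertype.io import normalize_log


class TestTrainClassifier:
    def test_structure(self, small_classifier):
        clf = small_classifier
        assert sorted(clf.tree.labels()) == ["A", "B", "C"]
        for node in clf.tree.internal_nodes():
            assert node.node_id in clf.node_models
        n_base = len(clf.config.selections) * len(clf.config.metrics)
        for m in clf.node_models.values():
            assert len(m.base) == n_base

    def test_requires_two_types(self, small_expr, fast_config):
        expr, ann, _ = small_expr
        mono = CellAnnotation({c: "X" for c in expr.cell_ids})
        with pytest.raises(ValidationError):
            train_classifier(expr, mono, fast_config)

    def test_deterministic(self, small_expr, fast_config):
        expr, ann, _ = small_expr
        a = train_classifier(expr, ann, fast_config)
        b = train_classifier(expr, ann, fast_config)
        assert a.tree.to_newick() == b.tree.to_newick()
        for na, nb in zip(a.node_models.values(), b.node_models.values()):
            assert np.array_equal(na.alpha_vector, nb.alpha_vector)


class TestPredict:
    def test_reference_cells_memorized(self, small_classifier, small_expr):
        expr, ann, _ = small_expr
        sub = expr.subset_cells(expr.cell_ids[::10])
        recs = predict(small_classifier, sub)
        for r in recs:
            assert r.outcome == "leaf"
            assert r.final_label == ann[r.cell_id]

    def test_outcome_partition(self, small_classifier, small_query):
        expr, _ = small_query
        recs = predict(small_classifier, expr)
        assert len(recs) == expr.n_cells
        for r in recs:
            assert r.outcome in ("leaf", "intermediate", "unassigned")
            if r.outcome == "leaf":
                assert isinstance(r.final_label, str)
            elif r.outcome == "intermediate":
                assert isinstance(r.final_label, frozenset)
                assert len(r.path) >= 1
            else:
                assert r.final_label == "unassigned"
                assert r.path == []

    def test_held_out_accuracy(self, small_classifier, small_query):
        expr, ann = small_query
        recs = predict(small_classifier, expr)
        correct = [
            r.final_label == ann[r.cell_id] for r in recs if r.outcome == "leaf"
        ]
        assert len(correct) > 0.9 * expr.n_cells
        assert np.mean(correct) > 0.95

    def test_gene_overlap_floor(self, small_classifier, small_query):
        expr, _ = small_query
        # rename most genes so the model's universe is missing
        renamed = ExpressionMatrix(
            expr.values,
            [f"other{i}" for i in range(expr.n_genes)],
            expr.cell_ids,
            expr.normalized,
        )
        with pytest.raises(ValidationError, match="missing"):
            predict(small_classifier, renamed)

    def test_missing_genes_tolerated_above_floor(
        self, small_classifier, small_query
    ):
        expr, ann = small_query
        universe = small_classifier.gene_universe()
        drop = set(universe[:len(universe) // 10])  # drop 10% of model genes
        keep = [g for g in expr.gene_ids if g not in drop]
        sub = expr.subset_genes(keep)
        recs = predict(small_classifier, sub)
        correct = [
            r.final_label == ann[r.cell_id] for r in recs if r.outcome == "leaf"
        ]
        assert np.mean(correct) > 0.9

    def test_records_frame_shape(self, small_classifier, small_query):
        expr, _ = small_query
        df = records_to_frame(predict(small_classifier, expr))
        assert list(df.columns) == [
            "cell_id", "final_label", "outcome", "path", "score", "levels",
        ]
        assert len(df) == expr.n_cells


class TestJointPredict:
    def test_singleton_equals_predict(self, small_classifier, small_query):
        expr, _ = small_query
        single = records_to_frame(predict(small_classifier, expr))
        joint = records_to_frame(joint_predict([small_classifier], expr))
        pd.testing.assert_frame_equal(single, joint)

    def test_duplicate_references_identical(self, small_classifier, small_query):
        expr, _ = small_query
        single = records_to_frame(predict(small_classifier, expr))
        dup = records_to_frame(
            joint_predict([small_classifier, small_classifier], expr)
        )
        pd.testing.assert_frame_equal(single, dup)

    def test_empty_model_list_raises(self, small_query):
        with pytest.raises(ValueError):
            joint_predict([], small_query[0])

    def test_label_map_translates(self, small_classifier, small_query):
        expr, ann = small_query
        recs = joint_predict(
            [small_classifier], expr, label_map={"A": "alpha"}
        )
        labels = {r.final_label for r in recs if r.outcome == "leaf"}
        assert "alpha" in labels and "A" not in labels


class TestMonotoneThresholds:
    def test_raising_weight_threshold_never_adds_leaves(
        self, small_expr, small_query, fast_config
    ):
        """Cells rejected at a lenient weight threshold stay rejected at a
        stricter one."""
        expr, ann, _ = small_expr
        q, _ = small_query
        leaf_sets = []
        for wt in (0.5, 0.7, 0.9):
            cfg = RunConfig(**{**fast_config.to_dict(), "weight_threshold": wt})
            clf = train_classifier(expr, ann, cfg)
            recs = predict(clf, q)
            leaf_sets.append({r.cell_id for r in recs if r.outcome == "leaf"})
        assert leaf_sets[1] <= leaf_sets[0]
        assert leaf_sets[2] <= leaf_sets[1]


class TestPosthocCluster:
    def test_two_planted_types_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        from hiertype import PopulationSpec

        spec = PopulationSpec(
            tree_blueprint={"X": None, "Y": None},
            cells_per_type=80,
            n_genes=800,
            markers_per_category=15,
            seed=8,
        )
        counts, ann, _ = simulate_dataset(spec)
        expr = normalize_log(counts)
        labels, markers = posthoc_cluster(expr, seed=0)
        truth = ann.label_array(expr.cell_ids)
        assert adjusted_rand_score(truth, labels) > 0.9
        assert not markers.empty
        # the top-ranked markers are genuinely discriminative genes
        for _, grp in markers.groupby("cluster"):
            assert (grp.head(5)["effect"].abs() > 1.0).all()
            assert (grp.head(5)["adj_p"] < 1e-6).all()

    def test_few_cells_single_cluster(self, rng):
        expr = ExpressionMatrix(
            rng.normal(0, 1, (50, 6)), [f"g{i}" for i in range(50)],
            [f"c{i}" for i in range(6)],
        )
        with pytest.warns(UserWarning):
            labels, markers = posthoc_cluster(expr)
        assert set(labels) == {0}
        assert markers.empty
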