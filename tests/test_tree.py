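import numpy as np
import pytest
from sklearn.base import clone

from irnv.schema import FATAL, SLIGHT
from irnv.synthetic import SyntheticConfig, generate_dataset, make_fixture
from irnv.tree import (
    CredalDecisionTreeClassifier,
    IRNVConfig,
    build_tree,
    classify_instance,
    iter_leaves,
    tree_depth,
    tree_to_dict,
    tree_to_text,
)

from helpers import tiny_dataset


def leaf_weight_error(clf):
    """|sum of leaf class-count weights - root total weight|."""
    if clf.tree_ is None:
        return 0.0
    root_total = sum(clf.tree_.class_counts)
    leaf_total = sum(sum(leaf.class_counts) for _, leaf in iter_leaves(clf.tree_))
    return abs(root_total - leaf_total)


class TestBuildTree:
    def test_perfect_predictor_gives_pure_stump(self):
        ds = make_fixture("pure_split")
        clf = build_tree(ds, "X1", "igr")
        assert clf.tree_.split_variable == "X1"
        for _, leaf in iter_leaves(clf.tree_):
            assert min(leaf.class_counts) == 0.0
        assert (clf.predict(ds) == ds.severity).all()

    def test_forced_noise_root_recovers_signal_below(self):
        """Root forced to noise X2: the second level must split on X1 and
        classify the 12-record fixture perfectly."""
        ds = make_fixture("forced_root")
        clf = build_tree(ds, "X2", "igr")
        assert clf.tree_.split_variable == "X2"
        assert tree_depth(clf.tree_) == 2
        for child in clf.tree_.branches.values():
            assert child.split_variable == "X1"
        assert (clf.predict(ds) == ds.severity).all()

    def test_constant_forced_root_yields_single_leaf(self):
        ds = tiny_dataset({"X": [1] * 6, "Y": [1, 2] * 3}, [1, 1, 1, 1, 2, 2])
        clf = build_tree(ds, "X", "igr")
        assert clf.tree_.is_leaf
        assert clf.tree_.leaf_class == SLIGHT

    def test_negative_imprecise_root_vetoes_tree(self, iig_negative):
        clf = build_tree(iig_negative, "X", "iig")
        assert clf.is_empty_ and clf.tree_ is None
        assert clf.root_score_ < 0
        # the gain-ratio tree for the same root is not vetoed
        assert not build_tree(iig_negative, "X", "igr").is_empty_

    def test_no_variable_repeats_on_any_path(self, small_planted_run):
        _, dataset, _ = small_planted_run
        from irnv.schema import split_by_intersection

        inter, _ = split_by_intersection(dataset)
        clf = build_tree(inter, "ACT_TY", "igr")
        for path, _ in iter_leaves(clf.tree_):
            names = [v for v, _ in path]
            assert len(names) == len(set(names))

    def test_depth_cap_and_weight_conservation(self, small_planted_run):
        _, dataset, _ = small_planted_run
        from irnv.schema import split_by_intersection

        inter, _ = split_by_intersection(dataset)
        for crit in ("igr", "iig", "anpim"):
            clf = build_tree(inter, "SE", crit, IRNVConfig(max_depth=4))
            if clf.tree_ is None:
                continue
            assert tree_depth(clf.tree_) <= 4
            assert leaf_weight_error(clf) < 1e-6

    def test_min_leaf_weight_respected(self):
        # a 5-record branch cannot be split 4/1 when min_leaf_weight=2
        ds = tiny_dataset(
            {"X": [1, 1, 1, 1, 1], "Y": [1, 1, 1, 1, 2]}, [1, 1, 1, 1, 2]
        )
        clf = CredalDecisionTreeClassifier(
            criterion="igr", root_variable="Y", min_leaf_weight=2.0
        ).fit(ds, ds.severity)
        assert clf.tree_.is_leaf  # Y's split would give a weight-1 child

    def test_determinism(self, small_planted_run):
        _, dataset, _ = small_planted_run
        from irnv.schema import split_by_intersection

        inter, _ = split_by_intersection(dataset)
        a = build_tree(inter, "F_T", "igr")
        b = build_tree(inter, "F_T", "igr")
        assert tree_to_dict(a.tree_) == tree_to_dict(b.tree_)

    def test_separable_data_zero_training_error_without_depth_cap(self):
        ds = make_fixture("forced_root")
        clf = CredalDecisionTreeClassifier(
            criterion="igr", max_depth=10, root_variable="X2"
        ).fit(ds, ds.severity)
        assert (clf.predict(ds) == ds.severity).all()


class TestClassifyInstance:
    def test_single_leaf_tree_returns_majority(self):
        ds = tiny_dataset({"X": [1] * 5}, [1, 1, 1, 2, 2])
        clf = build_tree(ds, "X", "igr")
        assert classify_instance(clf, {"X": 1}) == SLIGHT
        assert classify_instance(clf, {"X": 2}) == SLIGHT

    def test_pure_fatal_path(self):
        ds = make_fixture("pure_split")
        clf = build_tree(ds, "X1", "igr")
        assert classify_instance(clf, {"X1": 2}) == FATAL

    def test_missing_split_value_follows_heavier_aggregate(self):
        # X=1 branch carries 8 slight, X=2 branch 2 fatal: a record missing X
        # aggregates to the heavier slight mass
        ds = tiny_dataset({"X": [1] * 8 + [2] * 2}, [1] * 8 + [2] * 2)
        clf = build_tree(ds, "X", "igr")
        assert classify_instance(clf, {"X": None}) == SLIGHT

    def test_unseen_value_falls_back_to_node_majority(self):
        ds = make_fixture("pure_split")
        clf = build_tree(ds, "X1", "igr")
        # value 3 never seen in training; class counts are balanced -> slight
        assert classify_instance(clf, {"X1": 3}) == SLIGHT

    def test_missing_on_forced_root_fixture(self):
        ds = make_fixture("forced_root")
        clf = build_tree(ds, "X2", "igr")
        # X2 missing fans out 50/50, X1 then decides both subtrees identically
        assert classify_instance(clf, {"X1": 2, "X2": None}) == FATAL
        assert classify_instance(clf, {"X1": 1, "X2": None}) == SLIGHT


class TestEstimatorContract:
    def test_get_set_params_and_clone(self):
        clf = CredalDecisionTreeClassifier(criterion="iig", s=2.0, max_depth=3)
        params = clf.get_params()
        assert params["criterion"] == "iig" and params["s"] == 2.0
        other = clone(clf).set_params(criterion="anpim")
        assert other.get_params()["criterion"] == "anpim"

    def test_rejects_bad_labels(self):
        ds = make_fixture("pure_split")
        with pytest.raises(ValueError):
            CredalDecisionTreeClassifier().fit(ds.frame, np.zeros(ds.n))

    def test_fit_accepts_plain_frame_and_arrays(self):
        ds = make_fixture("forced_root")
        clf = CredalDecisionTreeClassifier(criterion="igr").fit(ds.frame, ds.severity)
        assert (clf.predict(ds.frame) == ds.severity).all()
        proba = clf.predict_proba(ds.frame)
        assert proba.shape == (ds.n, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_text_and_dict_serialisation(self):
        ds = make_fixture("forced_root")
        clf = build_tree(ds, "X2", "igr")
        text = tree_to_text(clf.tree_)
        assert "X2 = 1" in text and "X1 = 2" in text
        d = tree_to_dict(clf.tree_)
        assert d["split_variable"] == "X2"
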