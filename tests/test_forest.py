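"""Causal forest: determinism, prediction, variable importance."""
import numpy as np
import pytest

from hteforest.forest import (
    CausalForest,
    ForestConfig,
    ImportanceTable,
    fit_forest,
    predict_cate,
    variable_importance,
)
from hteforest.tree import CausalTree, HonestFitConfig, SplitRule, TreeNode

from conftest import synthetic_cohort


def _small_forest(n_trees=20, seed=0, n=600, tau_fn=None):
    cohort = synthetic_cohort(n=n, p=4, seed=seed, tau_fn=tau_fn)
    cfg = ForestConfig(n_trees=n_trees, min_leaf_fraction=0.1,
                       min_arm_count=5, seed=seed)
    return cohort, fit_forest(cohort, ["x1", "x2", "x3", "x4"], "mace", cfg)


def test_forest_determinism():
    _, f1 = _small_forest(seed=5)
    _, f2 = _small_forest(seed=5)
    for t1, t2 in zip(f1.trees, f2.trees):
        assert t1.split_variable_sequence() == t2.split_variable_sequence()
        assert np.array_equal(t1.estimation_index_set, t2.estimation_index_set)
    _, f3 = _small_forest(seed=6)
    assert any(
        t1.split_variable_sequence() != t3.split_variable_sequence()
        for t1, t3 in zip(f1.trees, f3.trees))


def test_forest_subsampling_respects_strata():
    cohort, forest = _small_forest(n_trees=5, seed=1)
    labels = cohort.strata()
    for tree in forest.trees:
        sub = np.concatenate([tree.split_index_set, tree.estimation_index_set])
        for lab in np.unique(labels):
            expected = 0.5 * np.sum(labels == lab)
            got = np.sum(labels[sub] == lab)
            assert abs(got - expected) <= 1.5
        # split/estimation halves balanced within strata too
        for lab in np.unique(labels):
            a = np.sum(labels[tree.split_index_set] == lab)
            b = np.sum(labels[tree.estimation_index_set] == lab)
            assert abs(a - b) <= 1


def test_forest_eligible_covariate_counts():
    _, forest = _small_forest(n_trees=10, seed=2)
    for tree in forest.trees:
        assert len(tree.covariates) == 2  # ceil(0.5 * 4)
        assert set(tree.covariates) <= set(forest.covariates)


def test_stump_forest_prediction_constant():
    nodes = {0: TreeNode(0, 0, None, tau_hat=-0.05, n_treated=30,
                         n_control=30)}
    stump = CausalTree(nodes, ("x1",), "mace", HonestFitConfig(),
                       np.array([]), np.array([]))
    forest = CausalForest([stump] * 7, ForestConfig(n_trees=7), ("x1",),
                          "mace")
    cohort = synthetic_cohort(n=10, seed=3)
    pred = predict_cate(forest, cohort.df)
    assert np.allclose(pred, -0.05)
    assert predict_cate(forest, {"x1": 1.0}) == pytest.approx(-0.05)


def test_prediction_sign_agreement_on_planted_cate():
    tau_fn = lambda X: np.where(X[:, 0] < 0, 0.25, -0.25)
    cohort, forest = _small_forest(n_trees=150, seed=4, n=2500,
                                   tau_fn=tau_fn)
    test = synthetic_cohort(n=600, p=4, seed=99, tau_fn=tau_fn)
    pred = predict_cate(forest, test.df)
    truth = tau_fn(test.df[["x1", "x2", "x3", "x4"]].to_numpy())
    agree = np.mean(np.sign(pred) == np.sign(truth))
    assert agree >= 0.80


def test_variance_shrinks_with_more_trees():
    cohort, small = _small_forest(n_trees=10, seed=8, n=800)
    _, big = _small_forest(n_trees=300, seed=8, n=800)
    p_small = np.abs(predict_cate(small, cohort.df)).mean()
    p_big = np.abs(predict_cate(big, cohort.df)).mean()
    assert p_big < p_small  # null data: averaging shrinks |tau_hat|


def test_importance_single_variable_forest():
    nodes = {
        0: TreeNode(0, 0, SplitRule("x1", 0.0), 1, 2, 0.0, 10, 10),
        1: TreeNode(1, 1, None, tau_hat=0.1, n_treated=5, n_control=5),
        2: TreeNode(2, 1, None, tau_hat=-0.1, n_treated=5, n_control=5),
    }
    tree = CausalTree(nodes, ("x1", "x2"), "mace", HonestFitConfig(),
                      np.array([]), np.array([]))
    forest = CausalForest([tree, tree], ForestConfig(n_trees=2),
                          ("x1", "x2"), "mace")
    imp = variable_importance(forest)
    assert imp.importance_of("x1") == pytest.approx(1.0)
    assert imp.importance_of("x2") == 0.0
    assert imp.rank_of("x1") == 1


def test_importance_hand_computed_two_tree_forest():
    """Two trees with known split layout vs the hand-derived weights."""
    def tree_a():
        nodes = {
            0: TreeNode(0, 0, SplitRule("x1", 0.0), 1, 2, 0.0, 20, 20),
            1: TreeNode(1, 1, SplitRule("x2", 0.0), 3, 4, 0.0, 10, 10),
            2: TreeNode(2, 1, None, tau_hat=0.0, n_treated=10, n_control=10),
            3: TreeNode(3, 2, None, tau_hat=0.0, n_treated=5, n_control=5),
            4: TreeNode(4, 2, None, tau_hat=0.0, n_treated=5, n_control=5),
        }
        return CausalTree(nodes, ("x1", "x2", "x3"), "mace",
                          HonestFitConfig(), np.array([]), np.array([]))

    def tree_b():
        nodes = {
            0: TreeNode(0, 0, SplitRule("x3", 0.0), 1, 2, 0.0, 20, 20),
            1: TreeNode(1, 1, None, tau_hat=0.0, n_treated=10, n_control=10),
            2: TreeNode(2, 1, None, tau_hat=0.0, n_treated=10, n_control=10),
        }
        return CausalTree(nodes, ("x1", "x2", "x3"), "mace",
                          HonestFitConfig(), np.array([]), np.array([]))

    forest = CausalForest([tree_a(), tree_b()], ForestConfig(n_trees=2),
                          ("x1", "x2", "x3"), "mace")
    imp = variable_importance(forest)
    # depth-1 splits: x1 once, x3 once (share 1/2 each); depth-2: x2 only.
    # weights w_d = d^-2 normalized over depths 1..4.
    w = np.array([1.0, 0.25, 1 / 9, 1 / 16])
    w = w / w.sum()
    raw = {"x1": w[0] * 0.5, "x3": w[0] * 0.5, "x2": w[1] * 1.0}
    total = sum(raw.values())
    for v in ("x1", "x2", "x3"):
        assert imp.importance_of(v) == pytest.approx(raw[v] / total)


def test_importance_invariant_to_nonsplitting_relabel():
    _, forest = _small_forest(n_trees=30, seed=11)
    imp = variable_importance(forest)
    assert imp.table["importance"].sum() == pytest.approx(1.0)
    ranks = imp.table.sort_values("variable")["rank"].tolist()
    # relabeling covariates that never split does not perturb the others
    splitting = {v for (v, _) in forest.split_census()}
    for v in forest.covariates:
        if v not in splitting:
            assert imp.importance_of(v) == 0.0


def test_all_stump_forest_warns_all_zero():
    nodes = {0: TreeNode(0, 0, None, tau_hat=0.0, n_treated=5, n_control=5)}
    stump = CausalTree(nodes, ("x1", "x2"), "mace", HonestFitConfig(),
                       np.array([]), np.array([]))
    forest = CausalForest([stump], ForestConfig(n_trees=1), ("x1", "x2"),
                          "mace")
    with pytest.warns(UserWarning, match="no splits"):
        imp = variable_importance(forest)
    assert (imp.table["importance"] == 0).all()
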