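"""Honest causal tree: split search, growth, honesty, pruning, routing."""
import math

import numpy as np
import pandas as pd
import pytest

from hteforest.data import CohortTable
from hteforest.errors import (
    ConfigurationError,
    FitError,
    UnassignableRecordError,
    UndefinedEffectError,
)
from hteforest.tree import (
    CausalTree,
    HonestFitConfig,
    SplitRule,
    TreeNode,
    assign_leaf,
    best_split,
    grow_tree,
    leaf_tau,
    prune_at,
    prune_cv,
    route_cohort,
)

from conftest import synthetic_cohort


# ---------------------------------------------------------------------------
# leaf_tau
# ---------------------------------------------------------------------------

def test_leaf_tau_arithmetic():
    cohort = synthetic_cohort(n=20, seed=0)
    df = cohort.df.copy()
    df["arm"] = [1.0] * 10 + [0.0] * 10
    df["mace"] = [1.0] * 2 + [0.0] * 8 + [1.0] * 5 + [0.0] * 5
    cohort = CohortTable(df, cohort.dictionary, validate=False)
    tau, n1, n0 = leaf_tau(np.arange(20), cohort, "mace")
    assert tau == pytest.approx(-0.30)
    assert (n1, n0) == (10, 10)


def test_leaf_tau_independent_recomputation():
    cohort = synthetic_cohort(n=137, seed=7)
    rows = np.arange(cohort.n)
    tau, _, _ = leaf_tau(rows, cohort, "mace")
    df = cohort.df
    expected = (df.loc[df.arm == 1, "mace"].mean()
                - df.loc[df.arm == 0, "mace"].mean())
    assert tau == pytest.approx(expected, abs=1e-12)


def test_leaf_tau_single_arm_error():
    cohort = synthetic_cohort(n=30, seed=1)
    rows = np.flatnonzero(cohort.arm == 1)
    with pytest.raises(UndefinedEffectError):
        leaf_tau(rows, cohort, "mace")


# ---------------------------------------------------------------------------
# best_split vs exhaustive oracle
# ---------------------------------------------------------------------------

def oracle_best_split(rows, variables, cohort, min_leaf, min_arm,
                      outcome="mace"):
    """Independent exhaustive enumeration over every (variable, midpoint)."""
    df = cohort.df
    best = None
    for var in sorted(variables):
        x = df[var].to_numpy(float)[rows]
        t = df["arm"].to_numpy(int)[rows]
        y = df[outcome].to_numpy(float)[rows]
        for thr in np.unique(x)[:-1]:
            xs = np.sort(np.unique(x))
            mid = (thr + xs[xs > thr][0]) / 2.0
            left = x < mid
            right = ~left
            ok = (left.sum() >= min_leaf and right.sum() >= min_leaf)
            for side in (left, right):
                ok = ok and (t[side] == 1).sum() >= min_arm
                ok = ok and (t[side] == 0).sum() >= min_arm
            if not ok:
                continue
            tau_l = y[left & (t == 1)].mean() - y[left & (t == 0)].mean()
            tau_r = y[right & (t == 1)].mean() - y[right & (t == 0)].mean()
            score = left.sum() * right.sum() / len(rows) * (tau_l - tau_r) ** 2
            if best is None or score > best[2]:
                best = (var, mid, score)
    return best


@pytest.mark.parametrize("seed,n,p", [(0, 40, 2), (1, 60, 4), (2, 50, 3),
                                      (3, 60, 4), (4, 45, 2), (5, 60, 4)])
def test_best_split_matches_bruteforce(seed, n, p):
    cohort = synthetic_cohort(n=n, p=p, seed=seed,
                              tau_fn=lambda X: 0.4 * np.sign(X[:, 0]))
    rows = np.arange(n)
    variables = [f"x{i + 1}" for i in range(p)]
    config = HonestFitConfig(min_leaf_fraction=0.1, min_arm_count=2)
    min_leaf = math.ceil(0.1 * n)
    got = best_split(rows, variables, cohort, config)
    want = oracle_best_split(rows, variables, cohort, min_leaf, 2)
    if want is None:
        assert got is None
    else:
        assert got.variable == want[0]
        assert got.threshold == pytest.approx(want[1], abs=1e-12)


def test_best_split_recovers_planted_threshold():
    cohort = synthetic_cohort(
        n=400, p=1, seed=10,
        tau_fn=lambda X: np.where(X[:, 0] < 0, 0.4, -0.4))
    rule = best_split(np.arange(400), ["x1"], cohort,
                      HonestFitConfig(min_leaf_fraction=0.05, min_arm_count=5))
    assert rule.variable == "x1"
    assert abs(rule.threshold) < 0.25


def test_best_split_too_few_rows_returns_none():
    cohort = synthetic_cohort(n=100, seed=2)
    config = HonestFitConfig(min_leaf_fraction=0.3, min_arm_count=2)
    assert best_split(np.arange(20), ["x1"], cohort, config,
                      n_total=100) is None


def test_best_split_empty_eligible_is_config_error():
    cohort = synthetic_cohort(n=100, seed=2)
    with pytest.raises(ConfigurationError):
        best_split(np.arange(100), [], cohort, HonestFitConfig())


# ---------------------------------------------------------------------------
# grow_tree: honesty and structure
# ---------------------------------------------------------------------------

def _grown(seed=0, n=1000, tau_fn=None):
    cohort = synthetic_cohort(n=n, p=3, seed=seed, tau_fn=tau_fn)
    half = n // 2
    config = HonestFitConfig(min_leaf_fraction=0.1, min_arm_count=5, seed=seed)
    tree = grow_tree(cohort, ["x1", "x2", "x3"], "mace", config,
                     np.arange(half), np.arange(half, n))
    return cohort, tree


def test_grow_requires_disjoint_sets():
    cohort = synthetic_cohort(n=100, seed=3)
    config = HonestFitConfig()
    with pytest.raises(FitError):
        grow_tree(cohort, ["x1"], "mace", config,
                  np.arange(60), np.arange(50, 100))


def test_honesty_estimation_outcomes_do_not_change_structure():
    tau_fn = lambda X: np.where(X[:, 0] < 0, 0.3, -0.3)
    cohort, tree = _grown(seed=5, tau_fn=tau_fn)
    df = cohort.df.copy()
    est = tree.estimation_index_set
    rng = np.random.default_rng(0)
    df.loc[est, "mace"] = rng.permutation(df.loc[est, "mace"].to_numpy())
    permuted = CohortTable(df, cohort.dictionary, validate=False)
    config = tree.config
    tree2 = grow_tree(permuted, list(tree.covariates), "mace", config,
                      tree.split_index_set, est)
    assert tree.split_variable_sequence() == tree2.split_variable_sequence()


def test_estimation_counts_partition_estimation_set():
    cohort, tree = _grown(seed=6)
    total = sum(l.n_treated + l.n_control for l in tree.leaves())
    assert total == tree.estimation_index_set.size


def test_planted_two_subgroup_recovery():
    tau_fn = lambda X: np.where(X[:, 0] < 0, 0.35, -0.35)
    cohort, tree = _grown(seed=7, n=2000, tau_fn=tau_fn)
    assert tree.n_leaves >= 2
    assert tree.nodes[tree.root_id].split.variable == "x1"
    left = tree.nodes[tree.nodes[tree.root_id].left]
    right = tree.nodes[tree.nodes[tree.root_id].right]
    # leaf effects carry the planted signs on each side
    def side_tau(node):
        while not node.is_leaf:
            node = tree.nodes[node.left]
        return node.tau_hat
    assert side_tau(left) > 0 > side_tau(right)


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

def _hand_tree():
    nodes = {
        0: TreeNode(0, 0, SplitRule("x1", 0.0), 1, 2),
        1: TreeNode(1, 1, SplitRule("x2", 1.0), 3, 4),
        2: TreeNode(2, 1, None, tau_hat=0.1, n_treated=20, n_control=20),
        3: TreeNode(3, 2, None, tau_hat=-0.2, n_treated=15, n_control=15),
        4: TreeNode(4, 2, None, tau_hat=0.3, n_treated=15, n_control=15),
    }
    return CausalTree(nodes, ("x1", "x2"), "mace", HonestFitConfig(),
                      np.array([]), np.array([]))


def test_assign_leaf_manual_trace():
    tree = _hand_tree()
    cases = [
        ({"x1": -1.0, "x2": 0.5}, 3),
        ({"x1": -1.0, "x2": 1.5}, 4),
        ({"x1": 2.0, "x2": 0.0}, 2),
        ({"x1": 0.0, "x2": 0.0}, 2),   # at the threshold -> right child
        ({"x1": -0.5, "x2": 1.0}, 4),  # at the threshold -> right child
    ]
    for record, expected in cases:
        assert assign_leaf(tree, record) == expected


def test_assign_leaf_missing_covariate():
    tree = _hand_tree()
    with pytest.raises(UnassignableRecordError):
        assign_leaf(tree, {"x1": float("nan"), "x2": 0.0})
    with pytest.raises(UnassignableRecordError):
        assign_leaf(tree, {"x2": 0.0})


def test_route_cohort_matches_assign_leaf():
    tree = _hand_tree()
    cohort = synthetic_cohort(n=50, seed=9)
    leaf_ids = route_cohort(tree, cohort)
    for i in range(50):
        rec = cohort.df.iloc[i]
        assert leaf_ids[i] == assign_leaf(tree, rec)


def test_root_only_tree_routes_everything_to_root():
    nodes = {0: TreeNode(0, 0, None, tau_hat=0.0, n_treated=5, n_control=5)}
    tree = CausalTree(nodes, ("x1",), "mace", HonestFitConfig(),
                      np.array([]), np.array([]))
    cohort = synthetic_cohort(n=20, seed=1)
    assert (route_cohort(tree, cohort) == 0).all()


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _valued_tree():
    """Hand-built tree where both children beat the collapsed parent."""
    nodes = {
        0: TreeNode(0, 0, SplitRule("x1", 0.0), 1, 2, 0.0, 100, 100),
        1: TreeNode(1, 1, None, tau_hat=0.3, n_treated=50, n_control=50),
        2: TreeNode(2, 1, None, tau_hat=-0.3, n_treated=50, n_control=50),
    }
    return CausalTree(nodes, ("x1",), "mace", HonestFitConfig(),
                      np.array([]), np.array([]))


def test_prune_extremes():
    tree = _valued_tree()
    assert prune_at(tree, 0.0).n_leaves == 2          # lambda = 0: full tree
    assert prune_at(tree, 1e9).n_leaves == 1          # huge lambda: root only


def test_prune_cv_null_collapses_and_signal_survives():
    # null: no heterogeneity -> root-only
    cohort = synthetic_cohort(n=1200, p=3, seed=21)
    config = HonestFitConfig(min_leaf_fraction=0.08, min_arm_count=5, seed=0)
    tree = grow_tree(cohort, ["x1", "x2", "x3"], "mace", config,
                     np.arange(600), np.arange(600, 1200))
    pruned = prune_cv(tree, cohort, config)
    assert pruned.n_leaves <= 2
    # strong planted signal -> the x1 split survives pruning
    tau_fn = lambda X: np.where(X[:, 0] < 0, 0.35, -0.35)
    cohort2 = synthetic_cohort(n=2000, p=3, seed=22, tau_fn=tau_fn)
    tree2 = grow_tree(cohort2, ["x1", "x2", "x3"], "mace", config,
                      np.arange(1000), np.arange(1000, 2000))
    pruned2 = prune_cv(tree2, cohort2, config)
    assert pruned2.n_leaves >= 2
    assert pruned2.nodes[pruned2.root_id].split.variable == "x1"


def test_empty_lambda_grid_rejected():
    with pytest.raises(ConfigurationError):
        HonestFitConfig(lambda_grid=())


def test_tree_json_round_trip(tmp_path):
    tree = _hand_tree()
    path = tmp_path / "tree.json"
    tree.to_json(path)
    back = CausalTree.from_json(path)
    assert back.split_variable_sequence() == tree.split_variable_sequence()
    assert back.leaves()[0].tau_hat == tree.leaves()[0].tau_hat
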