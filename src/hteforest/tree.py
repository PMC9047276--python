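"""Honest causal trees: recursive partitioning that maximizes
treatment-effect heterogeneity, honest (split/estimate sample-separated)
leaf estimates, and cost-complexity pruning tuned by honest
cross-validation.

Splitting criterion
-------------------
At a node with rows R, candidate (variable, threshold) pairs partition R
into (L, R\\L). With the within-child difference-in-means effect estimates
tau_L and tau_R (justified by randomization, so no propensity adjustment),
the chosen split maximizes

    n_L * n_R / (n_L + n_R) * (tau_L - tau_R)^2

over all pairs whose children satisfy the minimum leaf size and the
per-arm minimum count. Candidate thresholds are midpoints between
consecutive distinct observed values of the splitting sample (so a 0/1
covariate gets the single threshold 0.5). Ties are broken toward the
lexicographically earlier variable name, then the lower threshold, so
builds are deterministic. Records exactly at a threshold go right.

Honesty
-------
Tree structure is grown on the split sample only; every node's effect
estimate and arm counts are then recomputed from the disjoint estimation
sample. Leaves whose estimation sample violates the per-arm minimum are
merged upward. Permuting outcomes within the estimation sample can change
the leaf estimates but never the structure.

Pruning
-------
Cost-complexity objective: sum over leaves of n_leaf * tau_hat^2 minus
lambda times the number of leaves. The penalty lambda is chosen by k-fold
cross-validation: per fold an honest tree is grown on the training part,
pruned at each candidate lambda, and scored on the held-out part with the
honest heterogeneity estimate sum(n_test * (2*tau_train*tau_test -
tau_train^2)) — an unbiased estimate of sum(n * tau^2) that is negative in
expectation for noise leaves. The lambda with the best mean held-out score
wins; ties go to the larger (simpler) lambda.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data import CohortTable, _stratified_half_indices
from .errors import (
    ConfigurationError,
    FitError,
    UndefinedEffectError,
    UnassignableRecordError,
)


@dataclass(frozen=True)
class SplitRule:
    """value < threshold goes left; value >= threshold goes right."""

    variable: str
    threshold: float


@dataclass
class TreeNode:
    id: int
    depth: int
    split: SplitRule | None = None
    left: int | None = None
    right: int | None = None
    tau_hat: float = math.nan
    n_treated: int = 0
    n_control: int = 0

    @property
    def is_leaf(self):
        return self.split is None


@dataclass(frozen=True)
class HonestFitConfig:
    """Tuning knobs for a single honest causal tree.

    min_leaf_fraction is a fraction of the tree's splitting-sample size
    (default 0.05, i.e. every leaf holds at least ~5% of the sample);
    min_arm_count guards the per-arm estimation counts in each leaf;
    lambda_grid are the candidate cost-complexity penalties; cv_folds the
    number of honest cross-validation folds used to pick lambda.
    """

    min_leaf_fraction: float = 0.05
    min_arm_count: int = 10
    mtry_fraction: float = 0.5
    lambda_grid: tuple = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_leaf_fraction < 0.5):
            raise ConfigurationError("min_leaf_fraction must be in (0, 0.5)")
        if not (0 < self.mtry_fraction <= 1):
            raise ConfigurationError("mtry_fraction must be in (0, 1]")
        grid = tuple(self.lambda_grid)
        if not grid:
            raise ConfigurationError("lambda_grid must be nonempty")
        if any(l < 0 for l in grid) or list(grid) != sorted(grid):
            raise ConfigurationError("lambda_grid must be sorted and >= 0")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        object.__setattr__(self, "lambda_grid", grid)


class CausalTree:
    """An honest causal tree: id-indexed nodes plus the index sets used."""

    def __init__(self, nodes, covariates, outcome, config,
                 split_index_set, estimation_index_set, root_id=0,
                 lambda_selected=None):
        self.nodes = dict(nodes)
        self.root_id = root_id
        self.covariates = tuple(covariates)
        self.outcome = outcome
        self.config = config
        self.split_index_set = np.asarray(split_index_set)
        self.estimation_index_set = np.asarray(estimation_index_set)
        self.lambda_selected = lambda_selected

    # -- structure accessors --------------------------------------------
    def leaves(self):
        """Leaves in depth-first left-to-right order."""
        out, stack = [], [self.root_id]
        while stack:
            node = self.nodes[stack.pop()]
            if node.is_leaf:
                out.append(node)
            else:
                stack.append(node.right)
                stack.append(node.left)
        return out

    @property
    def n_leaves(self):
        return len(self.leaves())

    @property
    def depth(self):
        return max(n.depth for n in self.nodes.values() if self._reachable(n.id))

    def _reachable(self, nid):
        cur = self.root_id
        ids = {cur}
        stack = [cur]
        while stack:
            n = self.nodes[stack.pop()]
            if not n.is_leaf:
                stack += [n.left, n.right]
                ids |= {n.left, n.right}
        return nid in ids

    def split_variable_sequence(self):
        """Pre-order sequence of (variable, threshold) for internal nodes."""
        out, stack = [], [self.root_id]
        while stack:
            node = self.nodes[stack.pop()]
            if not node.is_leaf:
                out.append((node.split.variable, node.split.threshold))
                stack.append(node.right)
                stack.append(node.left)
        return out

    # -- serialization ---------------------------------------------------
    def to_json(self, path=None):
        payload = {
            "root_id": self.root_id,
            "covariates": list(self.covariates),
            "outcome": self.outcome,
            "lambda_selected": self.lambda_selected,
            "nodes": [
                {
                    "id": n.id, "depth": n.depth,
                    "split": (
                        {"variable": n.split.variable,
                         "threshold": n.split.threshold}
                        if n.split else None),
                    "left": n.left, "right": n.right,
                    "tau_hat": None if math.isnan(n.tau_hat) else n.tau_hat,
                    "n_treated": n.n_treated, "n_control": n.n_control,
                }
                for n in self.nodes.values()
            ],
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, source):
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        nodes = {}
        for d in payload["nodes"]:
            split = (SplitRule(d["split"]["variable"], d["split"]["threshold"])
                     if d["split"] else None)
            tau = math.nan if d["tau_hat"] is None else d["tau_hat"]
            nodes[d["id"]] = TreeNode(
                d["id"], d["depth"], split, d["left"], d["right"],
                tau, d["n_treated"], d["n_control"])
        return cls(nodes, payload["covariates"], payload["outcome"],
                   HonestFitConfig(), np.array([], dtype=int),
                   np.array([], dtype=int), payload["root_id"],
                   payload.get("lambda_selected"))


# ---------------------------------------------------------------------------
# Effect estimation primitives
# ---------------------------------------------------------------------------

def _tau_counts(t, y):
    """(tau_hat, n_treated, n_control) from arm/outcome arrays; tau is NaN
    when either arm is absent."""
    n1 = int(t.sum())
    n0 = int(t.size - n1)
    if n1 == 0 or n0 == 0:
        return math.nan, n1, n0
    m1 = float(y[t == 1].mean())
    m0 = float(y[t == 0].mean())
    return m1 - m0, n1, n0


def leaf_tau(rows, cohort, outcome):
    """Difference-in-means treatment effect within ``rows``.

    Returns (tau_hat, n_treated, n_control); raises
    :class:`UndefinedEffectError` if an arm is absent.
    """
    rows = np.asarray(rows)
    t = cohort.arm[rows].astype(int)
    y = cohort.df[outcome].to_numpy(dtype=float)[rows]
    tau, n1, n0 = _tau_counts(t, y)
    if math.isnan(tau):
        raise UndefinedEffectError(
            f"arm absent in rows (treated={n1}, control={n0})")
    return tau, n1, n0


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------

def _best_split_sorted(Xcols, t, y, sorted_rows, variables, min_leaf, min_arm):
    """Exhaustive best split given per-variable pre-sorted row arrays.

    Returns (variable, threshold, score) or None. ``variables`` must be in
    lexicographic order so first-strictly-greater keeps the tie convention.
    """
    best = None
    for var in variables:
        idx = sorted_rows[var]
        n = idx.size
        if n < 2 * min_leaf:
            return None
        xs = Xcols[var][idx]
        ts = t[idx]
        ys = y[idx]
        ty = ts * ys
        ct1 = np.cumsum(ts)
        cy1 = np.cumsum(ty)
        ct0 = np.cumsum(1 - ts)
        cy0 = np.cumsum(ys - ty)
        T1, Y1 = ct1[-1], cy1[-1]
        T0, Y0 = ct0[-1], cy0[-1]
        lt1, ly1 = ct1[:-1], cy1[:-1]
        lt0, ly0 = ct0[:-1], cy0[:-1]
        rt1, ry1 = T1 - lt1, Y1 - ly1
        rt0, ry0 = T0 - lt0, Y0 - ly0
        left_n = np.arange(1, n)
        right_n = n - left_n
        valid = (
            (xs[1:] > xs[:-1])
            & (left_n >= min_leaf) & (right_n >= min_leaf)
            & (lt1 >= min_arm) & (lt0 >= min_arm)
            & (rt1 >= min_arm) & (rt0 >= min_arm)
        )
        if not valid.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            tau_l = ly1 / lt1 - ly0 / lt0
            tau_r = ry1 / rt1 - ry0 / rt0
            score = left_n * right_n / n * (tau_l - tau_r) ** 2
        score = np.where(valid, score, -np.inf)
        k = int(np.argmax(score))  # first max -> lowest threshold
        if best is None or score[k] > best[2]:
            thr = float((xs[k] + xs[k + 1]) / 2.0)
            best = (var, thr, float(score[k]))
    return best


def best_split(rows, eligible, cohort, config, outcome="mace", n_total=None):
    """Best (variable, threshold) over ``rows`` of a cohort, or None.

    ``n_total`` anchors the minimum leaf size (defaults to len(rows), i.e.
    the splitting-sample size when called at a tree root).
    """
    eligible = sorted(eligible)
    if not eligible:
        raise ConfigurationError("eligible covariate set is empty")
    rows = np.asarray(rows)
    if n_total is None:
        n_total = rows.size
    min_leaf = max(1, math.ceil(config.min_leaf_fraction * n_total))
    t = cohort.arm.astype(np.int64)
    y = cohort.df[outcome].to_numpy(dtype=float)
    Xcols = {v: cohort.df[v].to_numpy(dtype=float) for v in eligible}
    sorted_rows = {
        v: rows[np.argsort(Xcols[v][rows], kind="stable")] for v in eligible
    }
    out = _best_split_sorted(Xcols, t, y, sorted_rows, eligible,
                             min_leaf, config.min_arm_count)
    if out is None:
        return None
    return SplitRule(out[0], out[1])


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

def _grow_structure(Xcols, t, y, sorted_rows, variables, min_leaf, min_arm):
    """Grow greedy structure depth-first; returns (nodes, leaf_row_lists).

    ``sorted_rows`` maps variable -> row indices sorted by that variable
    (all mapping the same row set). Node ids follow pre-order, so leaves()
    enumerates left-to-right.
    """
    nodes = {}
    counter = [0]

    def recurse(sr, depth):
        nid = counter[0]
        counter[0] += 1
        n = sr[variables[0]].size
        choice = None
        if n >= 2 * min_leaf:
            choice = _best_split_sorted(Xcols, t, y, sr, variables,
                                        min_leaf, min_arm)
        if choice is None:
            rows = np.sort(sr[variables[0]])
            tau, n1, n0 = _tau_counts(t[rows], y[rows])
            nodes[nid] = TreeNode(nid, depth, None, None, None, tau, n1, n0)
            return nid
        var, thr, _ = choice
        left_sr, right_sr = {}, {}
        for v in variables:
            idx = sr[v]
            go_left = Xcols[var][idx] < thr
            left_sr[v] = idx[go_left]
            right_sr[v] = idx[~go_left]
        node = TreeNode(nid, depth, SplitRule(var, thr))
        nodes[nid] = node
        node.left = recurse(left_sr, depth + 1)
        node.right = recurse(right_sr, depth + 1)
        return nid

    recurse(sorted_rows, 0)
    return nodes


def _route_rows(nodes, root_id, Xcols, rows):
    """Map each row to its leaf id; NaN on a splitting covariate -> -1."""
    rows = np.asarray(rows)
    out = np.full(rows.size, -1, dtype=np.int64)

    def walk(nid, sel):
        node = nodes[nid]
        if node.is_leaf:
            out[sel] = nid
            return
        x = Xcols[node.split.variable][rows[sel]]
        nan = np.isnan(x)
        go_left = (x < node.split.threshold) & ~nan
        go_right = ~go_left & ~nan
        if go_left.any():
            walk(node.left, sel[go_left])
        if go_right.any():
            walk(node.right, sel[go_right])

    walk(root_id, np.arange(rows.size))
    return out


def _estimate_and_merge(nodes, root_id, Xcols, t, y, est_rows, min_arm):
    """Recompute every node's tau/counts from the estimation sample and
    merge leaves whose estimation sample violates the per-arm minimum."""
    # annotate each node with its estimation rows
    node_rows = {root_id: np.asarray(est_rows)}
    order = [root_id]
    for nid in order:
        node = nodes[nid]
        rows = node_rows[nid]
        tau, n1, n0 = _tau_counts(t[rows], y[rows]) if rows.size else (math.nan, 0, 0)
        node.tau_hat, node.n_treated, node.n_control = tau, n1, n0
        if not node.is_leaf:
            x = Xcols[node.split.variable][rows]
            go_left = x < node.split.threshold
            node_rows[node.left] = rows[go_left]
            node_rows[node.right] = rows[~go_left]
            order += [node.left, node.right]

    def resolve(nid):
        node = nodes[nid]
        if not node.is_leaf:
            ok = resolve(node.left) and resolve(node.right)
            if not ok:
                node.split = None
                node.left = None
                node.right = None
        if node.is_leaf:
            return node.n_treated >= min_arm and node.n_control >= min_arm
        return True

    resolve(root_id)


def grow_tree(cohort, covariates, outcome, config, split_set, estimation_set):
    """Grow an honest causal tree.

    Structure is grown greedily on ``split_set``; every node's effect and
    counts are then recomputed from ``estimation_set`` only, and leaves
    whose estimation sample violates min_arm_count are merged upward.
    The two index sets must be disjoint. Rows with missing values among
    ``covariates`` are dropped (complete-case, logged).
    """
    split_set = np.asarray(split_set)
    estimation_set = np.asarray(estimation_set)
    if np.intersect1d(split_set, estimation_set).size:
        raise FitError("split and estimation sets must be disjoint")
    if estimation_set.size == 0:
        raise FitError("estimation set is empty")
    covariates = sorted(covariates)
    complete = set(cohort.complete_rows(covariates).tolist())
    split_set = np.array([r for r in split_set if r in complete])
    estimation_set = np.array([r for r in estimation_set if r in complete])
    if split_set.size == 0 or estimation_set.size == 0:
        raise FitError("no complete-case rows left after dropping missing")

    t = cohort.arm.astype(np.int64)
    y = cohort.df[outcome].to_numpy(dtype=float)
    Xcols = {v: cohort.df[v].to_numpy(dtype=float) for v in covariates}
    min_leaf = max(1, math.ceil(config.min_leaf_fraction * split_set.size))
    sorted_rows = {
        v: split_set[np.argsort(Xcols[v][split_set], kind="stable")]
        for v in covariates
    }
    nodes = _grow_structure(Xcols, t, y, sorted_rows, covariates, min_leaf,
                            config.min_arm_count)
    _estimate_and_merge(nodes, 0, Xcols, t, y, estimation_set,
                        config.min_arm_count)
    return CausalTree(nodes, covariates, outcome, config,
                      split_set, estimation_set)


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------

def assign_leaf(tree, record):
    """Route one record (mapping or Series) to its leaf id."""
    node = tree.nodes[tree.root_id]
    while not node.is_leaf:
        var = node.split.variable
        try:
            value = record[var]
        except (KeyError, IndexError) as exc:
            raise UnassignableRecordError(f"record lacks covariate {var!r}") from exc
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise UnassignableRecordError(f"missing splitting covariate {var!r}")
        node = tree.nodes[node.left if value < node.split.threshold else node.right]
    return node.id


def route_cohort(tree, cohort, rows=None):
    """Vectorized routing; returns per-row leaf ids, -1 for unassignable."""
    if rows is None:
        rows = np.arange(cohort.n)
    Xcols = {v: cohort.df[v].to_numpy(dtype=float)
             for v, _ in tree.split_variable_sequence()}
    if not Xcols:  # root-only tree
        return np.full(np.asarray(rows).size, tree.root_id, dtype=np.int64)
    return _route_rows(tree.nodes, tree.root_id, Xcols, rows)


# ---------------------------------------------------------------------------
# Cost-complexity pruning with honest cross-validation
# ---------------------------------------------------------------------------

def prune_at(tree, lam):
    """Prune ``tree`` at penalty ``lam`` (dynamic program on stored
    estimation-sample values). Collapses a subtree only when the collapsed
    leaf value is strictly better, so lam = 0 keeps any split whose
    children match or beat their parent."""

    collapsed = set()

    def value(nid):
        node = tree.nodes[nid]
        n = node.n_treated + node.n_control
        tau = 0.0 if math.isnan(node.tau_hat) else node.tau_hat
        leaf_value = n * tau * tau - lam
        if node.is_leaf:
            return leaf_value
        child_value = value(node.left) + value(node.right)
        if leaf_value > child_value:
            collapsed.add(nid)
            return leaf_value
        return child_value

    value(tree.root_id)

    new_nodes = {}

    def copy(nid, drop):
        node = tree.nodes[nid]
        drop = drop or nid in collapsed
        if node.is_leaf or nid in collapsed:
            new_nodes[nid] = TreeNode(nid, node.depth, None, None, None,
                                      node.tau_hat, node.n_treated,
                                      node.n_control)
        else:
            new_nodes[nid] = TreeNode(nid, node.depth, node.split, node.left,
                                      node.right, node.tau_hat,
                                      node.n_treated, node.n_control)
            copy(node.left, drop)
            copy(node.right, drop)

    copy(tree.root_id, False)
    return CausalTree(new_nodes, tree.covariates, tree.outcome, tree.config,
                      tree.split_index_set, tree.estimation_index_set,
                      tree.root_id, lambda_selected=lam)


def _holdout_score(tree, Xcols, t, y, test_rows):
    """Honest held-out heterogeneity estimate for a (pruned) tree."""
    leaf_ids = _route_rows(tree.nodes, tree.root_id, Xcols, test_rows)
    score = 0.0
    for leaf in tree.leaves():
        sel = test_rows[leaf_ids == leaf.id]
        if sel.size == 0:
            continue
        tau_te, n1, n0 = _tau_counts(t[sel], y[sel])
        if math.isnan(tau_te) or math.isnan(leaf.tau_hat):
            continue
        tau_tr = leaf.tau_hat
        score += sel.size * (2.0 * tau_tr * tau_te - tau_tr * tau_tr)
    return score


def prune_cv(tree, cohort, config=None):
    """Choose lambda by honest k-fold cross-validation, then prune.

    Per fold: the training part is halved (stratified by study x arm) into
    structure/estimation samples, an honest tree is grown, pruned at each
    candidate lambda, and scored on the held-out part (see module
    docstring). The lambda with the highest mean held-out score wins, ties
    to the larger lambda; the input tree is then pruned at that lambda.
    """
    config = config or tree.config
    grid = tuple(config.lambda_grid)
    if not grid:
        raise ConfigurationError("lambda_grid must be nonempty")
    rows_all = np.concatenate([tree.split_index_set, tree.estimation_index_set])
    rows_all = np.sort(rows_all)
    labels = cohort.strata()[rows_all]
    t = cohort.arm.astype(np.int64)
    y = cohort.df[tree.outcome].to_numpy(dtype=float)
    Xcols = {v: cohort.df[v].to_numpy(dtype=float) for v in tree.covariates}

    n_folds = min(config.cv_folds, np.min(np.unique(labels, return_counts=True)[1]))
    n_folds = max(2, n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=config.seed)
    fold_scores = []
    rng = np.random.default_rng(config.seed)
    for train_pos, test_pos in skf.split(rows_all, labels):
        train_rows = rows_all[train_pos]
        test_rows = rows_all[test_pos]
        struct, est = _stratified_half_indices(
            labels[train_pos], train_rows, rng)
        try:
            fold_tree = grow_tree(cohort, tree.covariates, tree.outcome,
                                  config, struct, est)
        except FitError:
            continue
        fold_scores.append([
            _holdout_score(prune_at(fold_tree, lam), Xcols, t, y, test_rows)
            for lam in grid])
    fold_scores = np.asarray(fold_scores)
    if fold_scores.size == 0:
        return prune_at(tree, grid[-1])
    totals = fold_scores.sum(axis=0)
    best = max(range(len(grid)), key=lambda i: (totals[i], grid[i]))
    # one-standard-error rule: prefer the largest lambda whose paired CV
    # score is within one SE of the best (standard cost-complexity
    # practice; guards against keeping noise splits the noisy CV score
    # cannot distinguish from real structure)
    chosen = best
    k = fold_scores.shape[0]
    for i in range(len(grid) - 1, best, -1):
        diff = fold_scores[:, best] - fold_scores[:, i]
        se = diff.std(ddof=1) / math.sqrt(k) if k > 1 else 0.0
        if diff.mean() <= se:
            chosen = i
            break
    return prune_at(tree, grid[chosen])
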