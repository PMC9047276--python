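"""Double-sample causal forest: an ensemble of honest causal trees grown on
stratified half-subsamples with per-tree covariate subsetting, CATE
prediction by averaging leaf estimates, and depth-weighted split-frequency
variable importance.

Each tree draws a study x arm stratified subsample (without replacement),
halves it into split/estimation samples, draws ceil(p/2) covariates once,
and grows an unpruned honest tree. Prediction for a record is the average
of the estimation-sample leaf effects over the trees whose leaf estimate is
defined. Variable importance is the split frequency of each variable at
depths 1..importance_max_depth, weighted by depth^-importance_decay_exponent
and normalized to sum to one — the depth-weighted split-count statistic
popularized by generalized random forests.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CohortTable, _stratified_half_indices
from .errors import ConfigurationError, FitError, NoPredictionError
from .tree import (
    CausalTree,
    HonestFitConfig,
    TreeNode,
    _estimate_and_merge,
    _grow_structure,
    _route_rows,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForestConfig:
    """Forest tuning knobs.

    The published analysis used 5000 trees; 500 is the desk-scale default
    and is exposed everywhere. min_leaf_fraction applies to each tree's own
    splitting-sample size.
    """

    n_trees: int = 500
    subsample_fraction: float = 0.5
    mtry_fraction: float = 0.5
    min_leaf_fraction: float = 0.05
    min_arm_count: int = 10
    importance_max_depth: int = 4
    importance_decay_exponent: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        for name in ("subsample_fraction", "mtry_fraction", "min_leaf_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.importance_max_depth < 1:
            raise ConfigurationError("importance_max_depth must be >= 1")

    def tree_config(self, seed=0):
        return HonestFitConfig(
            min_leaf_fraction=self.min_leaf_fraction,
            min_arm_count=self.min_arm_count,
            mtry_fraction=self.mtry_fraction,
            seed=seed,
        )


class CausalForest:
    def __init__(self, trees, config, covariates, outcome):
        self.trees = list(trees)
        self.config = config
        self.covariates = tuple(covariates)
        self.outcome = outcome

    def __len__(self):
        return len(self.trees)

    def leaf_counts(self):
        return np.array([t.n_leaves for t in self.trees])

    def split_census(self):
        """(variable, depth) -> split count across all trees."""
        census = {}
        for tree in self.trees:
            for node in tree.nodes.values():
                if node.is_leaf:
                    continue
                key = (node.split.variable, node.depth + 1)
                census[key] = census.get(key, 0) + 1
        return census


class ImportanceTable:
    """Per-variable depth-weighted split-frequency importance.

    Importances sum to 1 when any split exists; ranks (1 = most important)
    break ties lexicographically by variable name.
    """

    def __init__(self, variables, importances):
        order = np.lexsort((list(variables), -np.asarray(importances)))
        ranks = np.empty(len(variables), dtype=int)
        ranks[order] = np.arange(1, len(variables) + 1)
        self.table = pd.DataFrame(
            {"variable": list(variables),
             "importance": np.asarray(importances, dtype=float),
             "rank": ranks}
        ).sort_values("rank").reset_index(drop=True)

    @property
    def variables(self):
        return self.table["variable"].tolist()

    def importance_of(self, variable):
        row = self.table[self.table["variable"] == variable]
        if row.empty:
            raise KeyError(variable)
        return float(row["importance"].iloc[0])

    def rank_of(self, variable):
        row = self.table[self.table["variable"] == variable]
        if row.empty:
            raise KeyError(variable)
        return int(row["rank"].iloc[0])

    def top(self, k):
        return self.table.head(k)["variable"].tolist()

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_forest(cohort, covariates, outcome, config):
    """Fit a double-sample causal forest. Deterministic given config.seed."""
    covariates = sorted(covariates)
    p = len(covariates)
    if p < 2:
        raise ConfigurationError("need at least 2 covariates")
    analysis_rows = cohort.complete_rows(covariates)
    dropped = cohort.n - analysis_rows.size
    if dropped:
        log.info("fit_forest: dropped %d incomplete rows of %d", dropped, cohort.n)
    if analysis_rows.size < 40:
        raise FitError("need at least 40 complete rows to fit a forest")

    t = cohort.arm.astype(np.int64)
    y = cohort.df[outcome].to_numpy(dtype=float)
    Xcols = {v: cohort.df[v].to_numpy(dtype=float) for v in covariates}
    # forest-wide presort of the analysis rows per variable; per-tree sorted
    # subsets are obtained by stable membership filtering (no re-sorting)
    global_sorted = {
        v: analysis_rows[np.argsort(Xcols[v][analysis_rows], kind="stable")]
        for v in covariates
    }
    labels_all = cohort.strata()
    labels = labels_all[analysis_rows]
    n_max = int(cohort.n)
    m_eligible = max(2, math.ceil(config.mtry_fraction * p))

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_trees)
    trees = []
    for child in children:
        rng = np.random.default_rng(child)
        # stratified subsample without replacement
        sub = []
        for lab in np.unique(labels):
            stratum = analysis_rows[labels == lab]
            k = max(2, round(config.subsample_fraction * stratum.size))
            sub.append(rng.choice(stratum, size=k, replace=False))
        sub = np.concatenate(sub)
        sub_labels = labels_all[sub]
        split_set, est_set = _stratified_half_indices(sub_labels, sub, rng)
        eligible = sorted(rng.choice(covariates, size=m_eligible, replace=False))

        member = np.zeros(n_max, dtype=bool)
        member[split_set] = True
        sorted_rows = {
            v: global_sorted[v][member[global_sorted[v]]] for v in eligible
        }
        min_leaf = max(1, math.ceil(config.min_leaf_fraction * split_set.size))
        nodes = _grow_structure(Xcols, t, y, sorted_rows, eligible, min_leaf,
                                config.min_arm_count)
        _estimate_and_merge(nodes, 0, Xcols, t, y, est_set,
                            config.min_arm_count)
        trees.append(CausalTree(nodes, eligible, outcome,
                                config.tree_config(), split_set, est_set))
    return CausalForest(trees, config, covariates, outcome)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_cate(forest, records):
    """Average estimation-sample leaf effect over the ensemble.

    ``records`` is a DataFrame (or single mapping/Series) holding every
    forest covariate. Trees whose reached leaf has an undefined estimate
    are skipped; a record skipped by every tree raises
    :class:`NoPredictionError`.
    """
    single = not isinstance(records, pd.DataFrame)
    if single:
        records = pd.DataFrame([dict(records)])
    n = len(records)
    Xcols = {v: records[v].to_numpy(dtype=float) for v in forest.covariates}
    total = np.zeros(n)
    count = np.zeros(n)
    rows = np.arange(n)
    for tree in forest.trees:
        leaf_ids = _route_rows(tree.nodes, tree.root_id, Xcols, rows)
        taus = np.array([
            tree.nodes[i].tau_hat if i >= 0 else math.nan for i in leaf_ids
        ])
        ok = ~np.isnan(taus) & (leaf_ids >= 0)
        total[ok] += taus[ok]
        count[ok] += 1
    if np.any(count == 0):
        raise NoPredictionError(
            f"{int((count == 0).sum())} record(s) skipped by every tree")
    out = np.clip(total / count, -1.0, 1.0)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------

def variable_importance(forest):
    """Depth-weighted split-frequency importance, normalized to sum 1.

    importance(v) is proportional to
    sum_d w_d * splits_d(v) / total_splits_d over d = 1..max_depth with
    w_d proportional to d^-decay; variables that never split get 0.
    """
    cfg = forest.config
    depths = np.arange(1, cfg.importance_max_depth + 1)
    w = depths.astype(float) ** -cfg.importance_decay_exponent
    w /= w.sum()
    census = forest.split_census()
    total_at_depth = {int(d): 0 for d in depths}
    for (_, d), c in census.items():
        if d in total_at_depth:
            total_at_depth[d] += c
    raw = {}
    for v in forest.covariates:
        s = 0.0
        for j, d in enumerate(depths):
            tot = total_at_depth[int(d)]
            if tot:
                s += w[j] * census.get((v, int(d)), 0) / tot
        raw[v] = s
    total = sum(raw.values())
    if total == 0:
        warnings.warn("forest has no splits; importance table is all zero")
        return ImportanceTable(list(raw), [0.0] * len(raw))
    return ImportanceTable(list(raw), [raw[v] / total for v in raw])
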