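"""Summary causal tree and mutually exclusive subgroups.

Translates forest variable importance into one representative honest causal
tree: the top-k variables by importance are the eligible splitters, a single
honest tree is grown on a stratified half of the pooled cohort (estimated on
the other half), pruned by honest cross-validation, and its leaves define
the subgroups. A stability check refits the tree for several k (sharing the
structure seed) and reports whether the split-variable sequences agree.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import stratified_half_sample
from .errors import ConfigurationError
from .tree import (
    CausalTree,
    HonestFitConfig,
    SplitRule,
    grow_tree,
    prune_at,
    prune_cv,
    route_cohort,
)


def top_k_variables(importance, k):
    """The k highest-importance variables (ties lexicographic).

    If fewer than k variables have positive importance the set is reduced
    with a warning.
    """
    table = importance.table
    positive = table[table["importance"] > 0]
    if k > len(positive):
        warnings.warn(
            f"only {len(positive)} variables have positive importance; "
            f"requested top {k}")
        k = len(positive)
    return positive.head(k)["variable"].tolist()


def fit_summary_tree(cohort, top_vars, outcome="mace", config=None):
    """One honest causal tree on the pooled cohort restricted to top_vars.

    Structure is grown on a stratified (study x arm) half, estimated on the
    other half, pruned via honest cross-validation; any terminal node whose
    share of the full cohort falls below min_leaf_fraction is merged upward.
    """
    if not top_vars:
        raise ConfigurationError("top_vars must be nonempty")
    config = config or HonestFitConfig()
    struct, est = stratified_half_sample(cohort, config.seed)
    tree = grow_tree(cohort, top_vars, outcome, config, struct, est)
    tree = prune_cv(tree, cohort, config)
    return _enforce_total_share(tree, cohort, config.min_leaf_fraction)


def _enforce_total_share(tree, cohort, min_fraction):
    """Merge leaves whose share of the full cohort is below min_fraction."""
    while True:
        leaf_ids = route_cohort(tree, cohort)
        assigned = leaf_ids[leaf_ids >= 0]
        leaves = tree.leaves()
        if len(leaves) == 1:
            return tree
        shares = {l.id: np.mean(assigned == l.id) for l in leaves}
        bad = [l.id for l in leaves if shares[l.id] < min_fraction]
        if not bad:
            return tree
        # collapse the parent of the worst-offending leaf
        worst = min(bad, key=lambda i: shares[i])
        parent = next(n for n in tree.nodes.values()
                      if not n.is_leaf and worst in (n.left, n.right))
        parent.split = None
        parent.left = None
        parent.right = None


@dataclass
class StabilityReport:
    """Pairwise comparison of summary trees fitted at different k."""

    k_values: list
    sequences: dict            # k -> list of (variable, threshold)
    pairwise: dict             # (k_a, k_b) -> {match, max_threshold_diff}
    stable: bool

    def to_json(self, path=None):
        payload = {
            "k_values": list(self.k_values),
            "stable": self.stable,
            "sequences": {str(k): [[v, t] for v, t in seq]
                          for k, seq in self.sequences.items()},
            "pairwise": {f"{a},{b}": d for (a, b), d in self.pairwise.items()},
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def stability_check(cohort, importance, k_values, outcome="mace", config=None):
    """Fit one summary tree per k (shared structure seed) and compare.

    Verdict "stable" iff every pair of k values yields the identical
    pre-order split-variable sequence; thresholds of matched splits are
    compared and their maximum absolute difference reported.
    """
    if not k_values:
        raise ConfigurationError("k_values must be nonempty")
    config = config or HonestFitConfig()
    sequences, trees = {}, {}
    for k in k_values:
        tree = fit_summary_tree(cohort, top_k_variables(importance, k),
                                outcome, config)
        trees[k] = tree
        sequences[k] = tree.split_variable_sequence()
    pairwise = {}
    stable = True
    ks = list(k_values)
    for i, a in enumerate(ks):
        for b in ks[i + 1:]:
            vars_a = [v for v, _ in sequences[a]]
            vars_b = [v for v, _ in sequences[b]]
            match = vars_a == vars_b
            if match and vars_a:
                diff = max(abs(ta - tb) for (_, ta), (_, tb)
                           in zip(sequences[a], sequences[b]))
            else:
                diff = math.nan if not match else 0.0
            pairwise[(a, b)] = {"match": match,
                                "max_threshold_diff": diff}
            stable = stable and match
    return StabilityReport(ks, sequences, pairwise, stable), trees


# ---------------------------------------------------------------------------
# Subgroup assignment
# ---------------------------------------------------------------------------

@dataclass
class SubgroupAssignment:
    """Mapping of cohort rows to mutually exclusive subgroups.

    Subgroup ids are 1..G in depth-first left-to-right leaf order.
    ``definition`` gives, per subgroup, the conjunction of half-open
    conditions (variable, op in {lt, ge}, threshold) along the path.
    """

    labels: np.ndarray          # per-row subgroup id, 0 = unassigned
    definition: dict            # id -> list of (variable, op, threshold)
    shares: dict                # id -> fraction of assigned rows
    n_unassigned: int

    @property
    def n_subgroups(self):
        return len(self.definition)

    def rows(self, subgroup_id):
        return np.flatnonzero(self.labels == subgroup_id)

    def rules_text(self):
        """Human-readable one-line-per-subgroup rule list."""
        lines = []
        for gid in sorted(self.definition):
            conds = self.definition[gid]
            if conds:
                text = " AND ".join(
                    f"{v} {'<' if op == 'lt' else '>='} {thr:g}"
                    for v, op, thr in conds)
            else:
                text = "(all records)"
            lines.append(f"{text} -> subgroup {gid} "
                         f"(share {self.shares[gid]:.1%})")
        return "\n".join(lines)

    def to_json(self, path=None):
        payload = {
            "definition": {str(g): [[v, op, thr] for v, op, thr in conds]
                           for g, conds in self.definition.items()},
            "shares": {str(g): s for g, s in self.shares.items()},
            "n_unassigned": self.n_unassigned,
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def matches(self, df):
        """Re-derive per-row subgroup ids from the stored definitions."""
        out = np.zeros(len(df), dtype=int)
        for gid, conds in self.definition.items():
            mask = np.ones(len(df), dtype=bool)
            for v, op, thr in conds:
                x = df[v].to_numpy(dtype=float)
                mask &= (x < thr) if op == "lt" else (x >= thr)
            out[mask] = gid
        return out


def assign_subgroups(tree, cohort):
    """Leaf-order subgroup assignment over the full cohort."""
    leaves = tree.leaves()
    leaf_to_gid = {leaf.id: i + 1 for i, leaf in enumerate(leaves)}

    # path conditions per leaf
    definition = {}

    def walk(nid, conds):
        node = tree.nodes[nid]
        if node.is_leaf:
            definition[leaf_to_gid[nid]] = list(conds)
            return
        s = node.split
        walk(node.left, conds + [(s.variable, "lt", s.threshold)])
        walk(node.right, conds + [(s.variable, "ge", s.threshold)])

    walk(tree.root_id, [])

    leaf_ids = route_cohort(tree, cohort)
    labels = np.array([leaf_to_gid.get(i, 0) for i in leaf_ids])
    assigned = labels[labels > 0]
    shares = {g: float(np.mean(assigned == g)) if assigned.size else 0.0
              for g in leaf_to_gid.values()}
    return SubgroupAssignment(labels, definition, shares,
                              int((labels == 0).sum()))
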