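"""Model/Results interface over the causal-forest HTE analysis.

:class:`CausalForestHTE` is built from a cohort (optionally via
``from_dataframe``); ``fit()`` runs the forest and returns a
:class:`CausalForestHTEResults` carrying the ensemble, the variable
importance table and everything derived from it — CATE predictions, the
summary subgroup tree, subgroup risk differences, incidence curves — plus
a ``summary()`` table.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CohortTable, Variable, VariableDictionary
from .effects import event_rate_table, subgroup_effect_table
from .errors import ConfigurationError
from .forest import ForestConfig, fit_forest, predict_cate, variable_importance
from .subgroups import assign_subgroups, fit_summary_tree, top_k_variables
from .survival import plot_incidence_panels, subgroup_km_curves
from .tree import HonestFitConfig


class CausalForestHTE:
    """Heterogeneous-treatment-effect model for a (pooled) randomized trial.

    Parameters
    ----------
    cohort : CohortTable
        Analysis table; the treatment arm must be randomized (the effect
        estimator is a plain difference in means).
    covariates : sequence of str, optional
        Splitting covariates; defaults to every dictionary covariate.
    outcome : str
        Binary outcome column (default "mace").
    add_study_indicator : bool
        Encode the study label as a binary covariate so it competes for
        splits (its importance is reported; ~0 when the pooled effect
        surface carries no between-study signal).
    """

    def __init__(self, cohort, covariates=None, outcome="mace",
                 config=None, add_study_indicator=False):
        if add_study_indicator:
            cohort = _with_study_indicator(cohort)
        self.cohort = cohort
        cov = list(covariates) if covariates is not None \
            else list(cohort.dictionary.covariates)
        if add_study_indicator and "study_indicator" not in cov:
            cov.append("study_indicator")
        self.covariates = sorted(cov)
        if outcome not in cohort.dictionary.outcomes:
            raise ConfigurationError(f"{outcome!r} is not an outcome variable")
        self.outcome = outcome
        self.config = config or ForestConfig()

    @classmethod
    def from_dataframe(cls, df, dictionary, **kwargs):
        """Build from a raw DataFrame plus a variable dictionary."""
        return cls(CohortTable(df, dictionary), **kwargs)

    def fit(self, n_trees=None, seed=None):
        cfg = self.config
        if n_trees is not None or seed is not None:
            cfg = ForestConfig(
                n_trees=n_trees if n_trees is not None else cfg.n_trees,
                subsample_fraction=cfg.subsample_fraction,
                mtry_fraction=cfg.mtry_fraction,
                min_leaf_fraction=cfg.min_leaf_fraction,
                min_arm_count=cfg.min_arm_count,
                importance_max_depth=cfg.importance_max_depth,
                importance_decay_exponent=cfg.importance_decay_exponent,
                seed=seed if seed is not None else cfg.seed,
            )
        forest = fit_forest(self.cohort, self.covariates, self.outcome, cfg)
        return CausalForestHTEResults(self, forest)


def _with_study_indicator(cohort):
    df = cohort.df.copy()
    studies = sorted(pd.unique(df[cohort.dictionary.study].astype(str)))
    if len(studies) < 2:
        raise ConfigurationError("study indicator needs >= 2 studies")
    df["study_indicator"] = (
        df[cohort.dictionary.study].astype(str) == studies[-1]
    ).astype(float)
    dictionary = cohort.dictionary
    if "study_indicator" not in dictionary:
        dictionary = dictionary.with_entries(
            Variable("study_indicator", "binary",
                     f"1={studies[-1]}", "covariate"))
    return CohortTable(df, dictionary, validate=False)


class CausalForestHTEResults:
    """Fitted causal forest plus the subgroup analysis derived from it."""

    def __init__(self, model, forest):
        self.model = model
        self.forest = forest
        self.importance = variable_importance(forest)
        self._summary_tree = None
        self._assignment = None

    # -- CATE ------------------------------------------------------------
    def predict_cate(self, records=None):
        """tau_hat(x) for new records (default: the analysis cohort)."""
        if records is None:
            records = self.model.cohort.df
        return predict_cate(self.forest, records)

    # -- subgroups -------------------------------------------------------
    def summary_tree(self, k=8, tree_config=None):
        """Honest summary causal tree on the top-k importance variables."""
        cfg = tree_config or HonestFitConfig(
            min_leaf_fraction=self.forest.config.min_leaf_fraction,
            min_arm_count=self.forest.config.min_arm_count,
            seed=self.forest.config.seed,
        )
        top = top_k_variables(self.importance, k)
        self._summary_tree = fit_summary_tree(
            self.model.cohort, top, self.model.outcome, cfg)
        self._assignment = None
        return self._summary_tree

    def subgroups(self, k=8, tree_config=None):
        if self._summary_tree is None:
            self.summary_tree(k, tree_config)
        if self._assignment is None:
            self._assignment = assign_subgroups(
                self._summary_tree, self.model.cohort)
        return self._assignment

    def subgroup_effects(self, outcomes=("mace", "mortality"), **kwargs):
        return subgroup_effect_table(self.subgroups(**kwargs),
                                     self.model.cohort, outcomes)

    def event_rates(self, outcome=None, **kwargs):
        return event_rate_table(self.subgroups(**kwargs), self.model.cohort,
                                outcome or self.model.outcome)

    def incidence_curves(self, **kwargs):
        return subgroup_km_curves(self.subgroups(**kwargs), self.model.cohort,
                                  event=self.model.outcome)

    def plot_incidence(self, path=None, **kwargs):
        curves, tests = self.incidence_curves(**kwargs)
        return plot_incidence_panels(curves, tests, path)

    # -- reporting -------------------------------------------------------
    def summary(self, top=10):
        """Plain-text report: forest settings, top variables, subgroups."""
        cohort = self.model.cohort
        arm = cohort.arm.astype(int)
        lines = [
            "Causal forest heterogeneous treatment effects",
            "=" * 54,
            f"outcome: {self.model.outcome}    n = {cohort.n} "
            f"(intensive {int(arm.sum())}, standard {int((1 - arm).sum())})",
            f"trees: {len(self.forest)}    covariates: "
            f"{len(self.forest.covariates)}    min leaf: "
            f"{self.forest.config.min_leaf_fraction:.0%} of the split sample",
            "",
            f"Top {top} variables by depth-weighted split importance:",
        ]
        for _, row in self.importance.table.head(top).iterrows():
            lines.append(f"  {row['rank']:>2}. {row['variable']:<24} "
                         f"{row['importance']:.4f}")
        if self._summary_tree is not None:
            assignment = self.subgroups()
            effects = subgroup_effect_table(assignment, cohort,
                                            (self.model.outcome,))
            pooled = effects[effects["sample"] == "pooled"]
            lines += ["", f"Summary tree: {self._summary_tree.n_leaves} "
                          "subgroups (pooled risk differences):"]
            for _, r in pooled.iterrows():
                if r["flag"] == "unavailable":
                    continue
                lines.append(
                    f"  subgroup {int(r['subgroup'])}: share "
                    f"{assignment.shares[int(r['subgroup'])]:.1%}  rd = "
                    f"{r['rd']*100:+.1f}% (95% CI {r['ci_low']*100:+.1f}, "
                    f"{r['ci_high']*100:+.1f})")
        return "\n".join(lines)
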