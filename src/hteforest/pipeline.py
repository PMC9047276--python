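"""Full analysis orchestration with a reproducibility manifest.

Stage sequence mirrors the published analysis: per-study forests first,
rank concordance between their importance tables (Kendall's tau-b), then a
pooled forest including a study indicator, the top-k stability check
(k = 8, 9, 10), the summary subgroup tree, subgroup risk differences (MACE
and mortality; pooled and per study), and per-subgroup cumulative
incidence with log-rank tests. Per-stage random state is derived from one
root seed via a counter scheme so inserting a stage never perturbs later
stages.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .covariates import derive_covariates
from .data import read_cohort_csv, write_cohort_csv
from .effects import event_rate_table, kendall_tau_b, subgroup_effect_table
from .errors import StageError
from .forest import ForestConfig, fit_forest, variable_importance
from .model import CausalForestHTE
from .simulate import GeneratorConfig, build_dictionary, default_config, generate_cohort
from .subgroups import assign_subgroups, stability_check
from .survival import curves_to_frame, plot_incidence_panels, subgroup_km_curves
from .tree import HonestFitConfig

log = logging.getLogger(__name__)


def _stage_seed(root_seed, counter):
    ss = np.random.SeedSequence([int(root_seed), int(counter)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)   # name, seconds, row counts
    outputs: dict = field(default_factory=dict)  # relative path -> sha256

    def add_stage(self, name, seconds, **counts):
        self.stages.append({"stage": name, "seconds": round(seconds, 3),
                            **counts})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"config_hash": self.config_hash, "seed": self.seed,
                 "version": self.version, "stages": self.stages,
                 "outputs": self.outputs}, fh, sort_keys=False)


def _load_inputs(config_path, seed):
    """Resolve the run configuration: either CSV paths or a generator."""
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict) and "cohort_csv" in raw:
        gen = default_config()  # dictionary template for the CSV schema
        dictionary = build_dictionary(gen)
        cohort = read_cohort_csv(raw["cohort_csv"], dictionary)
        return cohort, raw
    if isinstance(raw, dict) and "cells" in raw:
        gen = GeneratorConfig.from_dict(raw)
    else:
        gen = default_config()
    cohort = generate_cohort(gen, seed=seed)
    return cohort, raw if isinstance(raw, dict) else {}


def run_full_analysis(config_path, output_dir, n_trees=None, seed=1,
                      k_values=(8, 9, 10), summary_k=8):
    """Execute the full pipeline; returns the RunManifest.

    Any stage error aborts with the stage name; the partial manifest is
    still written to the output directory.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_sha256(config_path), int(seed), __version__)
    current = {"stage": "setup"}

    def stage(name):
        current["stage"] = name
        log.info("stage: %s", name)
        return time.perf_counter()

    outputs = {}

    def save(name, writer):
        path = out / name
        writer(path)
        outputs[name] = _sha256(path)

    try:
        t0 = stage("read_cohort_csv")
        cohort, raw = _load_inputs(config_path, _stage_seed(seed, 0))
        manifest.add_stage("read_cohort_csv", time.perf_counter() - t0,
                           rows=cohort.n)
        n_trees = n_trees or int(raw.get("n_trees", 500))

        t0 = stage("derive_covariates")
        cohort, hgi_model = derive_covariates(cohort)
        save("hgi_model.yaml", hgi_model.to_yaml)
        save("cohort.csv", lambda p: write_cohort_csv(cohort, p))
        manifest.add_stage("derive_covariates", time.perf_counter() - t0,
                           rows=cohort.n,
                           hgi_missing=cohort.n_missing("hgi"))

        studies = sorted(np.unique(cohort.study_labels).tolist())
        per_study_importance = {}
        for i, study in enumerate(studies):
            t0 = stage(f"forest_{study}")
            sub = cohort.subset(np.flatnonzero(cohort.study_labels == study))
            cfg = ForestConfig(n_trees=n_trees, seed=_stage_seed(seed, 10 + i))
            forest = fit_forest(sub, sub.dictionary.covariates, "mace", cfg)
            imp = variable_importance(forest)
            per_study_importance[study] = imp
            save(f"importance_{study}.csv", imp.to_csv)
            manifest.add_stage(f"forest_{study}", time.perf_counter() - t0,
                               rows=sub.n, trees=n_trees)

        t0 = stage("kendall_tau_b")
        a, b = (per_study_importance[s] for s in studies[:2])
        common = [v for v in a.variables if v in set(b.variables)]
        tau_b = kendall_tau_b([a.importance_of(v) for v in common],
                              [b.importance_of(v) for v in common])
        save("importance_concordance.json", lambda p: Path(p).write_text(
            json.dumps({"studies": studies[:2], "kendall_tau_b": tau_b,
                        "n_variables": len(common)}, indent=2)))
        manifest.add_stage("kendall_tau_b", time.perf_counter() - t0,
                           variables=len(common))

        t0 = stage("forest_pooled")
        model = CausalForestHTE(
            cohort, outcome="mace", add_study_indicator=True,
            config=ForestConfig(n_trees=n_trees, seed=_stage_seed(seed, 20)))
        results = model.fit()
        save("importance_pooled.csv", results.importance.to_csv)
        forest = results.forest
        save("forest_summary.json", lambda p: Path(p).write_text(json.dumps(
            {"n_trees": len(forest),
             "leaf_counts": forest.leaf_counts().tolist(),
             "split_census": {f"{v}@depth{d}": c for (v, d), c
                              in sorted(forest.split_census().items())}},
            indent=2)))
        manifest.add_stage("forest_pooled", time.perf_counter() - t0,
                           rows=cohort.n, trees=n_trees)

        t0 = stage("stability_check")
        tree_cfg = HonestFitConfig(seed=_stage_seed(seed, 30))
        report, _ = stability_check(model.cohort, results.importance,
                                    list(k_values), "mace", tree_cfg)
        save("stability.json", report.to_json)
        manifest.add_stage("stability_check", time.perf_counter() - t0,
                           stable=bool(report.stable))

        t0 = stage("summary_tree")
        tree = results.summary_tree(k=summary_k, tree_config=tree_cfg)
        save("summary_tree.json", tree.to_json)
        manifest.add_stage("summary_tree", time.perf_counter() - t0,
                           leaves=tree.n_leaves)

        t0 = stage("assign_subgroups")
        assignment = results.subgroups()
        save("subgroups.json", assignment.to_json)
        save("subgroup_rules.txt",
             lambda p: Path(p).write_text(assignment.rules_text() + "\n"))
        manifest.add_stage("assign_subgroups", time.perf_counter() - t0,
                           subgroups=assignment.n_subgroups,
                           unassigned=assignment.n_unassigned)

        t0 = stage("effect_tables")
        effects = subgroup_effect_table(assignment, model.cohort,
                                        ("mace", "mortality"))
        save("subgroup_effects.csv", lambda p: effects.to_csv(p, index=False))
        rates = event_rate_table(assignment, model.cohort, "mace")
        save("event_rates.csv", lambda p: rates.to_csv(p, index=False))
        manifest.add_stage("effect_tables", time.perf_counter() - t0,
                           rows=len(effects))

        t0 = stage("survival_curves")
        curves, tests = subgroup_km_curves(assignment, model.cohort)
        save("km_curves.csv",
             lambda p: curves_to_frame(curves).to_csv(p, index=False))
        save("logrank.json", lambda p: Path(p).write_text(json.dumps(
            {str(g): {"chi_square": c, "p_value": pv}
             for g, (c, pv) in tests.items()}, indent=2)))
        save("incidence_panels.png",
             lambda p: plot_incidence_panels(curves, tests, p))
        manifest.add_stage("survival_curves", time.perf_counter() - t0,
                           subgroups=len(tests))
    except Exception as exc:
        manifest.outputs = outputs
        manifest.to_yaml(out / "manifest.yaml")
        if isinstance(exc, StageError):
            raise
        raise StageError(current["stage"], exc) from exc

    manifest.outputs = outputs
    manifest.to_yaml(out / "manifest.yaml")
    return manifest
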