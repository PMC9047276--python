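"""Subgroup-level absolute risk differences with Wald confidence intervals,
event-rate ordering across subgroups, and Kendall's tau-b rank concordance
between importance tables.

The risk difference is p_intensive - p_standard in probability units, so a
negative value means fewer events under intensive control. Confidence
intervals are unadjusted Wald intervals on the two binomial proportions
(no continuity correction), truncated to [-1, 1]; a Bonferroni-adjusted
interval column is emitted alongside for transparency, but no multiplicity
adjustment is applied to the primary intervals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UndefinedEffectError

Z95 = 1.959963984540054


@dataclass
class SubgroupEffect:
    subgroup: int
    sample: str                 # pooled | ACCORD | VADT
    outcome: str
    n_int: int
    n_std: int
    events_int: int
    events_std: int
    p_int: float
    p_std: float
    rd: float
    ci_low: float
    ci_high: float
    flag: str = ""

    def as_dict(self):
        return {
            "subgroup": self.subgroup, "sample": self.sample,
            "outcome": self.outcome, "n_int": self.n_int,
            "n_std": self.n_std, "events_int": self.events_int,
            "events_std": self.events_std, "p_int": self.p_int,
            "p_std": self.p_std, "rd": self.rd, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "flag": self.flag,
        }


def risk_difference(events_int, n_int, events_std, n_std, z=Z95,
                    subgroup=0, sample="pooled", outcome="mace"):
    """Absolute risk difference with a Wald 95% CI, truncated to [-1, 1].

    Zero denominators raise :class:`UndefinedEffectError`; an all-zero (or
    all-one) pair of cells yields a zero-width interval flagged
    "degenerate".
    """
    if n_int < 1 or n_std < 1:
        raise UndefinedEffectError("both arms need at least one participant")
    if events_int < 0 or events_std < 0 or events_int > n_int or events_std > n_std:
        raise DomainError("event counts must lie in [0, n]")
    p_i = events_int / n_int
    p_s = events_std / n_std
    rd = p_i - p_s
    se = math.sqrt(p_i * (1 - p_i) / n_int + p_s * (1 - p_s) / n_std)
    lo = max(-1.0, rd - z * se)
    hi = min(1.0, rd + z * se)
    flag = "degenerate" if se == 0 else ""
    return SubgroupEffect(subgroup, sample, outcome, n_int, n_std,
                          int(events_int), int(events_std), p_i, p_s,
                          rd, lo, hi, flag)


def subgroup_effect_table(assignment, cohort, outcomes=("mace",),
                          bonferroni=True):
    """One SubgroupEffect row per subgroup x sample x outcome.

    Samples are the pooled cohort plus each study alone. Subgroups absent
    from a study sample are flagged "unavailable" (not zero). Returns a
    DataFrame; Bonferroni-widened intervals (across subgroups) are emitted
    alongside the primary Wald intervals.
    """
    arm = cohort.arm.astype(int)
    studies = sorted(np.unique(cohort.study_labels).tolist())
    samples = [("pooled", np.ones(cohort.n, dtype=bool))] + [
        (s, cohort.study_labels == s) for s in studies
    ]
    gids = sorted(assignment.definition)
    n_groups = max(1, len(gids))
    z_bonf = float(stats.norm.ppf(1 - 0.025 / n_groups))
    rows = []
    for outcome in outcomes:
        y = cohort.df[outcome].to_numpy(dtype=float)
        for sample_name, sample_mask in samples:
            for gid in gids:
                mask = sample_mask & (assignment.labels == gid)
                sel_i = mask & (arm == 1)
                sel_s = mask & (arm == 0)
                n_i, n_s = int(sel_i.sum()), int(sel_s.sum())
                if n_i == 0 or n_s == 0:
                    rows.append(SubgroupEffect(
                        gid, sample_name, outcome, n_i, n_s, 0, 0,
                        math.nan, math.nan, math.nan, math.nan, math.nan,
                        "unavailable").as_dict() | {
                            "ci_low_bonferroni": math.nan,
                            "ci_high_bonferroni": math.nan})
                    continue
                e_i = int(np.nansum(y[sel_i]))
                e_s = int(np.nansum(y[sel_s]))
                eff = risk_difference(e_i, n_i, e_s, n_s, subgroup=gid,
                                      sample=sample_name, outcome=outcome)
                row = eff.as_dict()
                if bonferroni:
                    wide = risk_difference(e_i, n_i, e_s, n_s, z=z_bonf)
                    row["ci_low_bonferroni"] = wide.ci_low
                    row["ci_high_bonferroni"] = wide.ci_high
                rows.append(row)
    return pd.DataFrame(rows)


def event_rate_table(assignment, cohort, outcome="mace"):
    """Per-subgroup event rates (all / standard / intensive), ordered by
    the overall rate — the ordering used to relate subgroup effects to
    underlying risk."""
    arm = cohort.arm.astype(int)
    y = cohort.df[outcome].to_numpy(dtype=float)
    rows = []
    for gid in sorted(assignment.definition):
        mask = assignment.labels == gid
        if not mask.any():
            continue
        rows.append({
            "subgroup": gid,
            "n": int(mask.sum()),
            "rate_all": float(np.nanmean(y[mask])),
            "rate_std": float(np.nanmean(y[mask & (arm == 0)]))
            if (mask & (arm == 0)).any() else math.nan,
            "rate_int": float(np.nanmean(y[mask & (arm == 1)]))
            if (mask & (arm == 1)).any() else math.nan,
        })
    df = pd.DataFrame(rows).sort_values("rate_all").reset_index(drop=True)
    df["rate_order"] = np.arange(1, len(df) + 1)
    return df


def kendall_tau_b(ranks_a, ranks_b):
    """Tie-corrected Kendall rank concordance, exact over all pairs.

    Raises :class:`DomainError` for unequal lengths, fewer than 2 items,
    or an all-tied vector (zero denominator).
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.size != b.size:
        raise DomainError("vectors must have equal length")
    if a.size < 2:
        raise DomainError("need at least 2 items")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DomainError("tau-b undefined for an all-tied vector")
    tau, _ = stats.kendalltau(a, b, variant="b")
    return float(tau)
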