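"""Per-subgroup, per-arm cumulative incidence (Kaplan-Meier complement)
with Greenwood pointwise bands, and the two-sample log-rank test.

Ties between events and censorings at the same time follow the standard
convention (events precede censorings). Pointwise 95% bands default to the
plain (untransformed) scale, clipped to [0, 1]; the log(-log) transform is
available by flag.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .errors import DomainError, UndefinedEffectError

Z95 = 1.959963984540054


@dataclass
class KMCurve:
    """Cumulative incidence 1 - S(t) on the distinct event times.

    times includes a leading 0 with incidence 0; incidence is
    non-decreasing, at_risk non-increasing; se is the Greenwood standard
    error of the incidence (equal to that of the survival estimate).
    """

    times: np.ndarray
    incidence: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    at_risk: np.ndarray

    def to_frame(self):
        return pd.DataFrame({
            "time": self.times, "incidence": self.incidence, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "at_risk": self.at_risk,
        })


def km_cumulative_incidence(times, events, loglog_bands=False):
    """Product-limit cumulative incidence with Greenwood 95% bands.

    Parameters
    ----------
    times, events : array-like
        Follow-up durations (>= 0) and event indicators (1 = event,
        0 = censored), equal length and nonempty.
    loglog_bands : bool
        Use the log(-log) (exponential Greenwood) transform for the bands
        instead of the plain scale.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DomainError("empty input")
    if times.size != events.size:
        raise DomainError("times and events must have equal length")
    if np.any(times < 0):
        raise DomainError("durations must be >= 0")

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table  # index: observed times; removed/observed/at_risk
    ev = table[table["observed"] > 0]
    d = ev["observed"].to_numpy(dtype=float)
    n = ev["at_risk"].to_numpy(dtype=float)
    t_ev = ev.index.to_numpy(dtype=float)

    surv = np.cumprod(1.0 - d / n)
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n > d, d / (n * (n - d)), np.nan))
    se = surv * np.sqrt(gw)
    se = np.where(np.isnan(se) & (surv == 0), 0.0, se)
    inc = 1.0 - surv

    if loglog_bands:
        # exponential Greenwood bands on S, mapped to incidence
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.log(-np.log(surv))
            se_theta = np.sqrt(gw) / np.abs(np.log(surv))
            s_lo = surv ** np.exp(Z95 * se_theta)
            s_hi = surv ** np.exp(-Z95 * se_theta)
        lo = np.clip(1.0 - s_hi, 0.0, 1.0)
        hi = np.clip(1.0 - s_lo, 0.0, 1.0)
    else:
        lo = np.clip(inc - Z95 * se, 0.0, 1.0)
        hi = np.clip(inc + Z95 * se, 0.0, 1.0)

    return KMCurve(
        times=np.concatenate([[0.0], t_ev]),
        incidence=np.concatenate([[0.0], inc]),
        se=np.concatenate([[0.0], se]),
        ci_low=np.concatenate([[0.0], lo]),
        ci_high=np.concatenate([[0.0], hi]),
        at_risk=np.concatenate([[times.size], n.astype(int)]),
    )


def log_rank_test(times_a, events_a, times_b, events_b):
    """Two-sample log-rank test; returns (chi_square, p_value), 1 df.

    Raises :class:`UndefinedEffectError` if either group is empty or no
    events occur in either group.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise UndefinedEffectError("both groups must be nonempty")
    if events_a.sum() + events_b.sum() == 0:
        raise UndefinedEffectError("no events in either group")
    res = _lifelines_logrank(times_a, times_b, event_observed_A=events_a,
                             event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def subgroup_km_curves(assignment, cohort, time="event_time", event="mace"):
    """Per subgroup x arm incidence curves plus the log-rank comparison.

    Returns (curves, tests): curves maps (subgroup, arm) -> KMCurve, tests
    maps subgroup -> (chi_square, p_value).
    """
    arm = cohort.arm.astype(int)
    t = cohort.df[time].to_numpy(dtype=float)
    e = cohort.df[event].to_numpy(dtype=float).astype(int)
    curves, tests = {}, {}
    for gid in sorted(assignment.definition):
        mask = assignment.labels == gid
        sel0 = mask & (arm == 0)
        sel1 = mask & (arm == 1)
        if not sel0.any() or not sel1.any():
            continue
        curves[(gid, 0)] = km_cumulative_incidence(t[sel0], e[sel0])
        curves[(gid, 1)] = km_cumulative_incidence(t[sel1], e[sel1])
        try:
            tests[gid] = log_rank_test(t[sel1], e[sel1], t[sel0], e[sel0])
        except UndefinedEffectError:
            tests[gid] = (math.nan, math.nan)
    return curves, tests


def curves_to_frame(curves):
    """Flatten a (subgroup, arm) -> KMCurve mapping to one DataFrame."""
    frames = []
    for (gid, arm), curve in sorted(curves.items()):
        df = curve.to_frame()
        df.insert(0, "subgroup", gid)
        df.insert(1, "arm", arm)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def plot_incidence_panels(curves, tests=None, path=None):
    """Fig-2-style panels: one per subgroup, standard vs intensive."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gids = sorted({g for g, _ in curves})
    ncol = min(4, max(1, len(gids)))
    nrow = math.ceil(len(gids) / ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False, sharex=True, sharey=True)
    colors = {0: "#d66", 1: "#2a2"}
    labels = {0: "standard", 1: "intensive"}
    for i, gid in enumerate(gids):
        ax = axes[i // ncol][i % ncol]
        for armv in (0, 1):
            c = curves.get((gid, armv))
            if c is None:
                continue
            ax.step(c.times, c.incidence, where="post",
                    color=colors[armv], label=labels[armv])
            ax.fill_between(c.times, c.ci_low, c.ci_high, step="post",
                            alpha=0.2, color=colors[armv])
        title = f"subgroup {gid}"
        if tests and gid in tests and not math.isnan(tests[gid][1]):
            title += f" (log-rank p={tests[gid][1]:.3f})"
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("years")
        ax.set_ylabel("cumulative incidence")
        if i == 0:
            ax.legend(fontsize=8)
    for j in range(len(gids), nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path
    return fig
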