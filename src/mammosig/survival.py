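"""Kaplan-Meier curves, log-rank tests (including the trend variant)
and Mantel-Haenszel hazard ratios for cluster-stratified tumor groups.

All statistics follow the standard censored time-to-event conventions:
censored subjects at an event time count as at risk at that time; the
log-rank chi-square is the score form (O - E)' V^-1 (O - E) on the
pooled event-time table with df = G - 1; the trend variant is the 1-df
statistic with ordered group scores; the hazard ratio is
(O_a/E_a)/(O_b/E_b) with a log-scale normal 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2


@dataclass
class SurvivalCurve:
    """Product-limit step function with per-event-time risk table."""

    event_times: np.ndarray  # distinct times with >= 1 event
    at_risk: np.ndarray  # n(t)
    events: np.ndarray  # d(t)
    survival: np.ndarray  # S(t), nonincreasing, S before first event = 1
    censor_times: np.ndarray

    def at(self, t: float) -> float:
        """S(t): the step-function value at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    observed: np.ndarray  # O_g
    expected: np.ndarray  # E_g
    statistic: float
    df: int
    p_value: float
    trend_scores: np.ndarray | None = None


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    reference: str = "b"


def _clean(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    return times, events.astype(int)


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator."""
    times, events = _clean(times, events)
    ev_times = np.unique(times[events == 1])
    at_risk = np.array([(times >= t).sum() for t in ev_times])
    d = np.array([((times == t) & (events == 1)).sum() for t in ev_times])
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk) if len(ev_times) else np.array([])
    return SurvivalCurve(
        event_times=ev_times,
        at_risk=at_risk,
        events=d,
        survival=surv,
        censor_times=np.sort(times[events == 0]),
    )


def _pooled_table(groups):
    """Per event time: total at risk/events and per-group at risk/events."""
    cleaned = [_clean(t, e) for t, e in groups]
    all_times = np.concatenate([t for t, _ in cleaned])
    all_events = np.concatenate([e for _, e in cleaned])
    ev_times = np.unique(all_times[all_events == 1])
    G = len(cleaned)
    n_gt = np.zeros((G, len(ev_times)))
    d_gt = np.zeros((G, len(ev_times)))
    for g, (t, e) in enumerate(cleaned):
        n_gt[g] = [(t >= u).sum() for u in ev_times]
        d_gt[g] = [((t == u) & (e == 1)).sum() for u in ev_times]
    return ev_times, n_gt, d_gt


def _oe_variance(groups):
    """O, E per group and the hypergeometric covariance matrix of O."""
    _, n_gt, d_gt = _pooled_table(groups)
    n_t = n_gt.sum(axis=0)
    d_t = d_gt.sum(axis=0)
    O = d_gt.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        E = np.nansum(np.where(n_t > 0, d_t * n_gt / n_t, 0.0), axis=1)
    G, T = n_gt.shape
    V = np.zeros((G, G))
    for ti in range(T):
        n, d = n_t[ti], d_t[ti]
        if n <= 1 or d == 0:
            continue
        factor = d * (n - d) / (n - 1)
        pi = n_gt[:, ti] / n
        V += factor * (np.diag(pi) - np.outer(pi, pi))
    return O, E, V


def logrank(groups, trend_scores=None) -> LogRankResult:
    """Log-rank test across >= 2 groups of (times, events).

    Without ``trend_scores``: the score chi-square with df = G - 1.
    With ordered scores c_g: the 1-df trend statistic
    ``(sum c_g (O_g - E_g))^2 / (c' V c)``.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    O, E, V = _oe_variance(groups)
    if O.sum() == 0:
        import warnings

        warnings.warn("no events in any group; log-rank p = 1")
        return LogRankResult(O, E, 0.0, len(groups) - 1, 1.0,
                             np.asarray(trend_scores, dtype=float)
                             if trend_scores is not None else None)
    diff = O - E
    if trend_scores is not None:
        c = np.asarray(trend_scores, dtype=float)
        if len(c) != len(groups):
            raise ValueError("one trend score per group required")
        num = float(c @ diff) ** 2
        den = float(c @ V @ c)
        stat = num / den if den > 0 else 0.0
        df = 1
    else:
        # drop the last group: V is singular (rows sum to 0)
        sub = np.linalg.pinv(V[:-1, :-1])
        stat = float(diff[:-1] @ sub @ diff[:-1])
        df = len(groups) - 1
    p = float(chi2.sf(stat, df))
    return LogRankResult(O, E, stat, df, p,
                         np.asarray(trend_scores, dtype=float)
                         if trend_scores is not None else None)


def hazard_ratio(group_a, group_b) -> HazardRatioResult:
    """Mantel-Haenszel hazard ratio of group a relative to group b.

    HR = (O_a/E_a) / (O_b/E_b); 95% CI on the log scale with standard
    error sqrt(1/E_a + 1/E_b).
    """
    O, E, _ = _oe_variance([group_a, group_b])
    if O.sum() == 0:
        raise ValueError("hazard ratio needs at least one event")
    if (E == 0).any():
        raise ValueError("zero expected events in one group")
    hr = (O[0] / E[0]) / (O[1] / E[1])
    se = np.sqrt(1.0 / E[0] + 1.0 / E[1])
    return HazardRatioResult(
        hr=float(hr),
        ci_low=float(hr * np.exp(-1.96 * se)),
        ci_high=float(hr * np.exp(1.96 * se)),
    )


@dataclass
class ClusterSurvivalReport:
    curves: dict
    logrank: LogRankResult
    trend: LogRankResult
    hazard_ratios: pd.DataFrame
    reference: object


def survival_by_cluster(
    records: pd.DataFrame,
    subtype_filter: str | None = None,
    clusters: list | None = None,
    reference=None,
) -> ClusterSurvivalReport:
    """KM curves, overall log-rank, trend test, and pairwise HRs.

    ``records`` needs assigned_cluster, subtype, os_time, os_event
    columns. Clusters are ordered by label for the trend test (equally
    spaced scores); pairwise hazard ratios are taken against
    ``reference`` (default: the lowest cluster label present).
    """
    rec = records.dropna(subset=["os_time", "os_event"])
    if subtype_filter is not None:
        rec = rec[rec["subtype"] == subtype_filter]
    if clusters is not None:
        rec = rec[rec["assigned_cluster"].isin(clusters)]
    present = sorted(rec["assigned_cluster"].unique())
    present = [k for k in present if (rec["assigned_cluster"] == k).sum() > 0]
    if len(present) < 2:
        raise ValueError("need at least two clusters with tumors after filtering")
    groups = {
        k: (
            rec.loc[rec["assigned_cluster"] == k, "os_time"].to_numpy(),
            rec.loc[rec["assigned_cluster"] == k, "os_event"].to_numpy(),
        )
        for k in present
    }
    curves = {k: km_curve(*g) for k, g in groups.items()}
    overall = logrank(list(groups.values()))
    trend = logrank(list(groups.values()),
                    trend_scores=np.arange(len(present), dtype=float))
    reference = present[0] if reference is None else reference
    hrs = []
    for k in present:
        if k == reference:
            continue
        res = hazard_ratio(groups[k], groups[reference])
        hrs.append({"cluster": k, "reference": reference, "hr": res.hr,
                    "ci_low": res.ci_low, "ci_high": res.ci_high})
    return ClusterSurvivalReport(
        curves=curves,
        logrank=overall,
        trend=trend,
        hazard_ratios=pd.DataFrame(hrs),
        reference=reference,
    )
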