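"""Kaplan-Meier curves, multi-group log-rank tests, O/E hazard ratios, and
pre/post-landmark comparisons for subgroup survival analysis.

Endpoints are time-to-event in years (disease-free or distant-metastasis-
free survival) with 0/1 event indicators, optionally truncated at an
administrative horizon (10 years by default in the pipeline): any event
after the horizon is recoded as censored at the horizon.

The log-rank machinery is built on an explicit risk-set tabulation: at each
distinct event time t, with n_t subjects at risk (n_gt in group g) and d_t
events, group g's expected count increments by d_t * n_gt / n_t and the
hypergeometric variance accumulates.  The same observed/expected (O/E)
decomposition yields the Mantel-Haenszel/Peto hazard ratio

    HR = (O_a / E_a) / (O_b / E_b),   Var(log HR) ~ 1/E_a + 1/E_b,

so no iterative model fitting is involved.  Kaplan-Meier estimation is
delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats


def _check_times(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be 1-D and equal length")
    if len(times) == 0:
        raise ValueError("empty survival group")
    if np.any(times <= 0):
        raise ValueError("non-positive event/censoring time")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0 or 1")
    return times, events


def apply_horizon(times, events, horizon):
    """Administrative truncation: events after ``horizon`` become censorings
    at the horizon."""
    times, events = _check_times(times, events)
    if horizon is None:
        return times, events
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    over = times > horizon
    return np.where(over, horizon, times), np.where(over, 0, events)


@dataclass
class KMCurve:
    event_times: np.ndarray    # distinct event times
    at_risk: np.ndarray        # n_t at each event time
    n_events: np.ndarray       # d_t at each event time
    survival: np.ndarray       # S(t) just after each event time
    horizon: float | None

    def at(self, t: float) -> float:
        """S(t): the product-limit estimate at time t."""
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return s


def km_estimate(times, events, horizon: float | None = None) -> KMCurve:
    """Product-limit survival estimate, optionally truncated at ``horizon``."""
    times, events = apply_horizon(times, events, horizon)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        event_times=ev.index.to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        n_events=ev["observed"].to_numpy(dtype=float),
        survival=surv.loc[ev.index].to_numpy(dtype=float),
        horizon=horizon,
    )


def oe_table(times, events, groups) -> pd.DataFrame:
    """Observed and expected event counts per group from the log-rank risk-set
    tabulation (ties share the same risk set)."""
    times, events = _check_times(times, events)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    g_idx = {g: i for i, g in enumerate(labels)}
    gi = np.array([g_idx[g] for g in groups])
    G = len(labels)

    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = int(((times == t) & (events == 1)).sum())
        n_gt = np.bincount(gi[at_risk], minlength=G).astype(float)
        d_gt = np.bincount(gi[(times == t) & (events == 1)], minlength=G).astype(float)
        O += d_gt
        E += d_t * n_gt / n_t
        if n_t > 1:
            p = n_gt / n_t
            mult = d_t * (n_t - d_t) / (n_t - 1)
            V += mult * (np.diag(p) - np.outer(p, p))
    return pd.DataFrame({"observed": O, "expected": E},
                        index=pd.Index(labels, name="group")), V


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame  # observed/expected per group


def logrank_test(times, events, groups) -> LogrankResult:
    """Standard (unweighted) k-group log-rank test."""
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValueError("need >= 2 groups")
    if int(np.sum(np.asarray(events, dtype=int))) == 0:
        raise ValueError("log-rank statistic undefined with zero events")
    table, V = oe_table(times, events, groups)
    diff = (table["observed"] - table["expected"]).to_numpy()
    # drop one group (sum of diffs is 0) and invert the reduced covariance
    sub = V[:-1, :-1]
    stat = float(diff[:-1] @ np.linalg.pinv(sub) @ diff[:-1])
    df = len(table) - 1
    p = float(stats.chi2.sf(stat, df))
    return LogrankResult(statistic=stat, df=df, p_value=p, table=table)


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    table: pd.DataFrame


def hazard_ratio(times_a, events_a, times_b, events_b,
                 alpha: float = 0.05) -> HazardRatioResult:
    """Mantel-Haenszel/Peto O/E hazard ratio of group a relative to group b,
    with a log-scale confidence interval from Var(log HR) = 1/E_a + 1/E_b."""
    times_a, events_a = _check_times(times_a, events_a)
    times_b, events_b = _check_times(times_b, events_b)
    if events_a.sum() == 0 or events_b.sum() == 0:
        raise ValueError("both groups need >= 1 event for a hazard ratio")
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    groups = np.array(["a"] * len(times_a) + ["b"] * len(times_b))
    table, V = oe_table(times, events, groups)
    Oa, Ea = table.loc["a", "observed"], table.loc["a", "expected"]
    Ob, Eb = table.loc["b", "observed"], table.loc["b", "expected"]
    if Ea == 0 or Eb == 0:
        raise ValueError("a group has zero expected events")
    hr = (Oa / Ea) / (Ob / Eb)
    se = np.sqrt(1.0 / Ea + 1.0 / Eb)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    log_hr = np.log(hr) if hr > 0 else -np.inf
    # two-sided p from the log-rank normal statistic for the 2-group case
    v = V[0, 0]
    z_stat = (Oa - Ea) / np.sqrt(v) if v > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z_stat)))
    return HazardRatioResult(
        hr=float(hr),
        ci_low=float(np.exp(log_hr - z * se)),
        ci_high=float(np.exp(log_hr + z * se)),
        p_value=p,
        table=table,
    )


@dataclass
class LandmarkResult:
    landmark: float
    pre: HazardRatioResult | None
    post: HazardRatioResult | None
    pre_events: pd.Series      # events in (0, landmark] per stratum
    post_events: pd.Series     # events after the landmark per stratum
    n_at_risk_post: pd.Series  # subjects event-free and uncensored at landmark


def split_at_landmark(times, events, landmark: float):
    """Split follow-up at the landmark.

    Pre-period: everyone, censored at the landmark if still event-free.
    Post-period: subjects still at risk at the landmark, with the clock
    reset to zero.
    """
    times, events = _check_times(times, events)
    if landmark <= 0:
        raise ValueError("landmark must be > 0")
    pre_t = np.minimum(times, landmark)
    pre_e = np.where(times <= landmark, events, 0)
    at_risk = times > landmark
    post_t = times[at_risk] - landmark
    post_e = events[at_risk]
    return (pre_t, pre_e), (post_t, post_e), at_risk


def landmark_compare(times, events, strata, landmark: float = 5.0) -> LandmarkResult:
    """Compare two strata (e.g. endocrine-treated vs not) separately before and
    after a landmark time.

    The pre-period hazard ratio uses all subjects with follow-up censored at
    the landmark; the post-period conditions on being event-free at the
    landmark with times reset.  When a period has no events in one stratum
    its HR is reported as None (the period event counts are always reported).
    """
    times, events = _check_times(times, events)
    strata = np.asarray(strata)
    labels = pd.unique(strata)
    if len(labels) != 2:
        raise ValueError("landmark comparison needs exactly 2 strata")
    (pre_t, pre_e), (post_t, post_e), at_risk = split_at_landmark(times, events, landmark)
    post_s = strata[at_risk]

    def _events_by(t, e, s):
        return pd.Series({lab: int(e[s == lab].sum()) for lab in labels})

    pre_events = _events_by(pre_t, pre_e, strata)
    post_events = _events_by(post_t, post_e, post_s)
    n_at_risk_post = pd.Series({lab: int((post_s == lab).sum()) for lab in labels})

    def _hr(t, e, s):
        a, b = labels[0], labels[1]
        try:
            return hazard_ratio(t[s == a], e[s == a], t[s == b], e[s == b])
        except ValueError:
            return None

    pre_hr = _hr(pre_t, pre_e, strata)
    post_hr = _hr(post_t, post_e, post_s) if at_risk.any() else None
    return LandmarkResult(landmark=landmark, pre=pre_hr, post=post_hr,
                          pre_events=pre_events, post_events=post_events,
                          n_at_risk_post=n_at_risk_post)
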