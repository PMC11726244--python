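"""Time-dependent survival evaluation suite.

Implements Antolini's time-dependent concordance index, subject-level
percentile bootstrap, cumulative/dynamic time-dependent AUC with inverse
probability of censoring weights (IPCW), Brier score and integrated Brier
score, 10-bin calibration with expected calibration error, the Kaplan-Meier
product-limit estimator, the two-group log-rank test, and median-threshold
risk stratification.

Conventions: at tied times events precede censorings; survival curves are
step-constant and right-continuous; the censoring distribution G is the
Kaplan-Meier estimate with the censoring indicator flipped, evaluated at a
left limit G(t-) for event weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import MetricResult

__all__ = [
    "KMCurve",
    "km_estimator",
    "km_survival_at",
    "censoring_km",
    "ctd_index",
    "bootstrap_ci",
    "td_auc",
    "brier_score",
    "integrated_brier",
    "ece_calibration",
    "logrank_test",
    "stratify_median",
    "step_lookup",
]


@dataclass
class KMCurve:
    event_times: np.ndarray  # distinct times with >= 1 event
    S_hat: np.ndarray        # survival immediately after each event time
    at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.S_hat) > 1e-12):
            raise ValueError("KM curve must be nonincreasing")


def km_estimator(times, events) -> KMCurve:
    """Product-limit estimator; events precede censorings at tied times."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    order = np.argsort(times, kind="stable")
    t_sorted, d_sorted = times[order], events[order]
    uniq = np.unique(t_sorted[d_sorted == 1])
    S, s_vals, at_risk, n_ev = 1.0, [], [], []
    for t in uniq:
        n_risk = int(np.sum(t_sorted >= t))
        d = int(np.sum((t_sorted == t) & (d_sorted == 1)))
        S *= 1.0 - d / n_risk
        s_vals.append(S)
        at_risk.append(n_risk)
        n_ev.append(d)
    return KMCurve(
        event_times=np.asarray(uniq),
        S_hat=np.asarray(s_vals),
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
    )


def km_survival_at(curve: KMCurve, t: float, left: bool = False) -> float:
    """S(t) (or the left limit S(t-)) from the step curve."""
    side = "left" if left else "right"
    j = int(np.searchsorted(curve.event_times, t, side=side)) - 1
    return 1.0 if j < 0 else float(curve.S_hat[j])


def censoring_km(times, events) -> KMCurve:
    """KM of the censoring distribution (indicator flipped)."""
    return km_estimator(times, 1 - np.asarray(events).astype(int))


def step_lookup(edges: np.ndarray, values: np.ndarray, t) -> np.ndarray:
    """Right-continuous step interpolation of per-edge values at times t."""
    j = np.searchsorted(edges, np.asarray(t, dtype=np.float64), side="right") - 1
    j = np.clip(j, 0, len(values) - 1)
    return values[..., j]


# ---------------------------------------------------------------------------
# discrimination


def ctd_index(surv: np.ndarray, edges: np.ndarray, times, events) -> float:
    """Antolini's time-dependent concordance.

    ``surv``: (n, len(edges)) predicted survival at the grid edges.  A pair
    (i, j) is comparable when i has an event and either T_i < T_j, or
    T_i = T_j with j censored.  It is concordant when S_i(T_i) < S_j(T_i);
    exact ties in the predictions count 1/2.  With step curves known at the
    grid edges, S(T_i) is the survival at the end of the (right-closed) bin
    containing T_i, matching the discretization convention.
    """
    surv = np.asarray(surv, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(int)
    n = len(times)
    if n < 2 or events.sum() < 1:
        raise ValueError("need >= 2 subjects and >= 1 event")
    bin_idx = np.clip(np.searchsorted(edges, times, side="left"), 1, surv.shape[1] - 1)
    conc, total = 0.0, 0
    for i in np.nonzero(events == 1)[0]:
        comp = (times > times[i]) | ((times == times[i]) & (events == 0))
        comp[i] = False
        if not comp.any():
            continue
        s_at_ti = surv[:, bin_idx[i]]
        si = s_at_ti[i]
        sj = s_at_ti[comp]
        conc += np.sum(si < sj) + 0.5 * np.sum(si == sj)
        total += int(comp.sum())
    if total == 0:
        raise ValueError("no comparable pairs")
    return float(conc / total)


def td_auc(scores, times, events, horizon: float = 36.0) -> float:
    """Cumulative/dynamic time-dependent AUC at ``horizon`` with IPCW.

    Cases: events by the horizon (weight 1/G(T_i-)); controls: subjects still
    at risk beyond it (weight 1/G(horizon)).  Without censoring this equals
    the rank-based AUC of the binary endpoint "event by horizon".
    """
    scores = np.asarray(scores, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(int)
    case = (times <= horizon) & (events == 1)
    ctrl = times > horizon
    if not case.any() or not ctrl.any():
        raise ValueError(f"no cases or no controls at horizon {horizon}")
    G = censoring_km(times, events)
    w_case = np.array([1.0 / km_survival_at(G, t, left=True) for t in times[case]])
    g_h = km_survival_at(G, horizon)
    if g_h <= 0 or not np.all(np.isfinite(w_case)):
        raise ValueError(f"censoring survival vanishes at or before horizon {horizon}")
    s_case, s_ctrl = scores[case], scores[ctrl]
    gt = (s_case[:, None] > s_ctrl[None, :]).astype(np.float64)
    eq = (s_case[:, None] == s_ctrl[None, :]).astype(np.float64)
    num = float(w_case @ (gt + 0.5 * eq) @ np.ones(len(s_ctrl)))
    den = float(w_case.sum() * len(s_ctrl))
    return num / den


# ---------------------------------------------------------------------------
# calibration / accuracy


def brier_score(surv: np.ndarray, edges: np.ndarray, times, events, t: float) -> float:
    """IPCW Brier score at time t: weighted mean of (1{T > t} - S(t))^2."""
    surv = np.asarray(surv, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(int)
    S_t = step_lookup(np.asarray(edges), surv, t) if surv.ndim == 2 else surv
    G = censoring_km(times, events)
    g_t = km_survival_at(G, t)
    if g_t <= 0:
        raise ValueError(f"censoring KM reaches 0 at or before evaluation time t={t}")
    contrib = np.zeros(len(times))
    died = (times <= t) & (events == 1)
    alive = times > t
    if died.any():
        g_left = np.array([km_survival_at(G, ti, left=True) for ti in times[died]])
        if np.any(g_left <= 0):
            raise ValueError(f"censoring KM reaches 0 before evaluation time t={t}")
        contrib[died] = (S_t[died] ** 2) / g_left
    if alive.any():
        contrib[alive] = ((1.0 - S_t[alive]) ** 2) / g_t
    return float(contrib.mean())


def integrated_brier(surv: np.ndarray, edges: np.ndarray, times, events, grid) -> float:
    """Trapezoidal integral of BS(t) over ``grid``, normalized by its span."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size < 2:
        raise ValueError("integration grid needs >= 2 points")
    bs = np.array([brier_score(surv, edges, times, events, t) for t in grid])
    return float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))


def ece_calibration(pred_surv_at_horizon, times, events, n_bins: int = 10,
                    horizon: float = 36.0, censoring_aware: bool = True):
    """Expected calibration error of predicted S(horizon) against observed
    event-free proportions.

    Subjects are binned on the predicted probability with equal-width bins;
    bins with fewer than 2 subjects merge into their lower neighbor.  The
    observed proportion per bin is the within-bin KM survival at the horizon
    (censoring-aware) or, with ``censoring_aware=False``, the plain fraction
    event-free among subjects not censored before the horizon.  ECE is the
    subject-count-weighted mean absolute discrepancy.  Returns
    ``(ece, per-bin table)``.
    """
    p = np.asarray(pred_surv_at_horizon, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(int)
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        raise ValueError("predictions must lie in [0, 1]")
    if np.ptp(p) == 0:
        groups = [np.arange(len(p))]
    else:
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        assign = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
        groups = [np.nonzero(assign == b)[0] for b in range(n_bins)]
        groups = [g for g in groups if g.size > 0]
        # merge undersized bins into the adjacent (lower-index) bin
        merged = []
        for g in groups:
            if merged and (g.size < 2 or merged[-1].size < 2):
                merged[-1] = np.concatenate([merged[-1], g])
            else:
                merged.append(g)
        groups = merged
    rows, ece, n = [], 0.0, len(p)
    for g in groups:
        if censoring_aware:
            km = km_estimator(times[g], events[g])
            obs = km_survival_at(km, horizon)
        else:
            keep = ~((events[g] == 0) & (times[g] <= horizon))
            obs = float(np.mean(times[g][keep] > horizon)) if keep.any() else np.nan
        pred = float(p[g].mean())
        rows.append({"n": int(g.size), "pred_mean": pred, "observed": obs})
        if np.isfinite(obs):
            ece += g.size / n * abs(pred - obs)
    return float(ece), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparison


def logrank_test(times_a, events_a, times_b, events_b):
    """Two-group log-rank test; returns (chi2, p) with 1 df."""
    ta, da = np.asarray(times_a, dtype=np.float64), np.asarray(events_a).astype(int)
    tb, db = np.asarray(times_b, dtype=np.float64), np.asarray(events_b).astype(int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if da.sum() + db.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    all_t = np.concatenate([ta, tb])
    all_d = np.concatenate([da, db])
    grp = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(all_t[all_d == 1]):
        at_risk = all_t >= t
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & (grp == 0)).sum())
        d_tot = int(((all_t == t) & (all_d == 1)).sum())
        d_a = int(((all_t == t) & (all_d == 1) & (grp == 0)).sum())
        e_a = d_tot * n_a / n_tot
        o_minus_e += d_a - e_a
        if n_tot > 1:
            var += d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def stratify_median(risks_validation, risks_test, times_test, events_test, horizon: float = 36.0):
    """Median-threshold risk stratification.

    The cut point is the median of the *validation* risk scores, applied
    unchanged to the test set (ties go to low-risk).  Returns a dict with the
    group assignment, per-group KM curves, the log-rank (chi2, p), and the
    event-free survival at the horizon per group.
    """
    rv = np.asarray(risks_validation, dtype=np.float64)
    if rv.size == 0:
        raise ValueError("validation risks must be nonempty")
    rt = np.asarray(risks_test, dtype=np.float64)
    times = np.asarray(times_test, dtype=np.float64)
    events = np.asarray(events_test).astype(int)
    threshold = float(np.median(rv))
    high = rt > threshold
    result = {"threshold": threshold, "group": np.where(high, "high", "low"),
              "km": {}, "efs_at_horizon": {}, "chi2": np.nan, "p": np.nan}
    for name, mask in (("low", ~high), ("high", high)):
        if mask.any():
            km = km_estimator(times[mask], events[mask])
            result["km"][name] = km
            result["efs_at_horizon"][name] = km_survival_at(km, horizon)
    if high.all() or (~high).all():
        warnings.warn("all test subjects fall on one side of the threshold; log-rank undefined")
        return result
    try:
        chi2, p = logrank_test(times[~high], events[~high], times[high], events[high])
        result["chi2"], result["p"] = chi2, p
    except ValueError as exc:
        warnings.warn(f"log-rank undefined: {exc}")
    return result


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_ci(statistic, n_subjects: int, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0, name: str = "statistic", max_redraws: int | None = None) -> MetricResult:
    """Subject-level percentile bootstrap.

    ``statistic`` maps an index array to a scalar; resamples on which it
    raises ``ValueError`` (e.g. no comparable pairs) are redrawn, with the
    total number of redraws capped (default 10 * n_boot).
    """
    rng = np.random.default_rng(seed)
    point = float(statistic(np.arange(n_subjects)))
    cap = 10 * n_boot if max_redraws is None else max_redraws
    vals, redraws = [], 0
    while len(vals) < n_boot:
        idx = rng.integers(0, n_subjects, size=n_subjects)
        try:
            vals.append(float(statistic(idx)))
        except ValueError:
            redraws += 1
            if redraws > cap:
                raise ValueError(f"bootstrap redraw cap exceeded ({cap})")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return MetricResult(name=name, point=point,
                        ci_low=float(min(lo, point)), ci_high=float(max(hi, point)),
                        n_boot=n_boot, seed=seed)
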