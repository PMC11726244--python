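"""Classical statistics for cohort description and covariate screening.

The cores are implemented directly so they can be verified against
enumeration oracles: Fisher's exact test sums hypergeometric probability
mass, the Wilcoxon rank-sum uses an exact dynamic-programming null
distribution for small samples (normal approximation with tie correction
otherwise), and univariable Cox regression maximizes the Breslow (or Efron)
partial likelihood with safeguarded Newton steps.  scipy supplies only the
reference distributions (hypergeometric pmf, chi-square/normal tails).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "CoxFit",
    "fisher_exact_2x2",
    "wilcoxon_ranksum",
    "cox_univariable",
    "cohort_table",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts; rows = category level, columns = cohort."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")


def fisher_exact_2x2(table: ContingencyTable2x2 | list | tuple | np.ndarray) -> float:
    """Two-sided Fisher exact p: total probability of tables (with the
    observed margins) no more likely than the observed one, with a
    1 + 1e-7 relative slack on the comparison."""
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = np.asarray(table, dtype=int)
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        warnings.warn("a margin of the 2x2 table is zero; p = 1")
        return 1.0
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def _ranksum_exact_counts(n: int, m: int) -> np.ndarray:
    """counts[s] = number of n-subsets of ranks 1..n+m with rank sum s."""
    N = n + m
    smax = n * N
    counts = np.zeros((n + 1, smax + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in range(1, N + 1):
        for j in range(min(r, n), 0, -1):
            counts[j, r:] += counts[j - 1, : smax + 1 - r]
    return counts[n]


def wilcoxon_ranksum(x, y) -> float:
    """Two-sided rank-sum test p-value.

    Exact enumeration (DP over the rank-sum null distribution) when
    min(n, m) <= 10 and there are no ties; otherwise a normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0
    n, m, N = x.size, y.size, x.size + y.size
    ranks = stats.rankdata(combined)
    w = float(ranks[:n].sum())
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if min(n, m) <= 10 and not has_ties:
        counts = _ranksum_exact_counts(n, m)
        total = counts.sum()
        wi = int(round(w))
        p_low = counts[: wi + 1].sum() / total
        p_high = counts[wi:].sum() / total
        return float(min(1.0, 2.0 * min(p_low, p_high)))
    mu = n * (N + 1) / 2.0
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1))
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


@dataclass
class CoxFit:
    beta: float
    hr: float
    se: float
    p_wald: float
    converged: bool

    def __post_init__(self) -> None:
        if self.hr <= 0 or not 0 <= self.p_wald <= 1:
            raise ValueError("invalid Cox fit")


def _cox_derivatives(beta: float, x: np.ndarray, times: np.ndarray, events: np.ndarray,
                     ties: str):
    """(loglik, score, information) of the partial likelihood at beta."""
    order = np.argsort(-times, kind="stable")  # descending: cumsums = risk sets
    xs, ts, ds = x[order], times[order], events[order]
    ex = np.exp(beta * xs)
    s0 = np.cumsum(ex)
    s1 = np.cumsum(xs * ex)
    s2 = np.cumsum(xs * xs * ex)
    ll = score = info = 0.0
    event_times = np.unique(ts[ds == 1])
    for t in event_times:
        in_risk = np.searchsorted(-ts, -t, side="right") - 1  # last index with time >= t
        tied = (ts == t) & (ds == 1)
        d = int(tied.sum())
        xsum = float(xs[tied].sum())
        S0, S1, S2 = s0[in_risk], s1[in_risk], s2[in_risk]
        if ties == "breslow" or d == 1:
            ll += beta * xsum - d * np.log(S0)
            score += xsum - d * S1 / S0
            info += d * (S2 / S0 - (S1 / S0) ** 2)
        elif ties == "efron":
            ex_t, x_t = ex[tied], xs[tied]
            T0, T1, T2 = ex_t.sum(), (x_t * ex_t).sum(), (x_t * x_t * ex_t).sum()
            ll += beta * xsum
            for l in range(d):
                f = l / d
                A0, A1, A2 = S0 - f * T0, S1 - f * T1, S2 - f * T2
                ll -= np.log(A0)
                score += xsum / d - A1 / A0
                info += A2 / A0 - (A1 / A0) ** 2
        else:
            raise ValueError(f"unknown tie handling {ties!r}")
    return ll, score, info


def cox_univariable(covariate, times, events, ties: str = "breslow",
                    max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Univariable Cox proportional-hazards fit by safeguarded Newton steps.

    Centers the covariate internally (the estimate is invariant to location
    shifts).  Monotone partial likelihood (complete separation) is flagged by
    ``converged=False``.
    """
    x = np.asarray(covariate, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(int)
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    if events.sum() < 2:
        raise ValueError("need >= 2 events")
    xc = (x - x.mean()) / max(x.std(), 1e-12)
    beta, converged = 0.0, False
    ll, score, info = _cox_derivatives(beta, xc, times, events, ties)
    for _ in range(max_iter):
        if info <= 1e-12:
            break
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_derivatives(new_beta, xc, times, events, ties)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_derivatives(new_beta, xc, times, events, ties)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(step) < tol:
            converged = True
            break
    if abs(beta) > 15.0:
        converged = False
    se_std = 1.0 / np.sqrt(max(info, 1e-300))
    # undo internal standardization
    beta_raw = beta / max(x.std(), 1e-12)
    se_raw = se_std / max(x.std(), 1e-12)
    z = beta / se_std if se_std > 0 else 0.0
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return CoxFit(beta=float(beta_raw), hr=float(np.exp(beta_raw)), se=float(se_raw),
                  p_wald=p, converged=converged)


# ---------------------------------------------------------------------------
# descriptive table


def _fisher_by_site(df: pd.DataFrame, flag: pd.Series) -> float:
    a = int(((df["site"] == "A") & flag).sum())
    b = int(((df["site"] == "B") & flag).sum())
    c = int(((df["site"] == "A") & ~flag).sum())
    d = int(((df["site"] == "B") & ~flag).sum())
    return fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))


def cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-site descriptive statistics with the appropriate test per row.

    Continuous rows report median [min, max] and a Wilcoxon rank-sum p;
    categorical rows report counts (percent) per level with a Fisher exact p
    on the level-vs-rest split (the first level carries the p-value).
    """
    sites = sorted(table["site"].unique())
    if len(sites) < 2:
        raise ValueError("cohort table requires >= 2 sites")
    a_df = table[table["site"] == "A"]
    b_df = table[table["site"] == "B"]
    rows = []

    def cont_row(name, col):
        pa, pb = a_df[col].to_numpy(), b_df[col].to_numpy()
        rows.append({
            "characteristic": name, "level": "",
            "site_A": f"[{pa.min():.1f},{pa.max():.1f}], {np.median(pa):.1f}",
            "site_B": f"[{pb.min():.1f},{pb.max():.1f}], {np.median(pb):.1f}",
            "p_value": wilcoxon_ranksum(pa, pb), "test": "wilcoxon",
        })

    def cat_row(name, col, levels):
        for i, lev in enumerate(levels):
            na, nb = int((a_df[col] == lev).sum()), int((b_df[col] == lev).sum())
            rows.append({
                "characteristic": name, "level": str(lev),
                "site_A": f"{na} ({100 * na / max(len(a_df), 1):.0f}%)",
                "site_B": f"{nb} ({100 * nb / max(len(b_df), 1):.0f}%)",
                "p_value": _fisher_by_site(table, table[col] == levels[0]) if i == 0 else np.nan,
                "test": "fisher" if i == 0 else "",
            })

    rows.append({"characteristic": "n", "level": "", "site_A": str(len(a_df)),
                 "site_B": str(len(b_df)), "p_value": np.nan, "test": ""})
    cont_row("age_years", "age_years")
    cat_row("sex", "sex", ["M", "F"])
    cat_row("resection", "resection", ["GTR", "STR", "biopsy", "NA"])
    cat_row("chemo", "chemo", [1, 0])
    cat_row("radiotherapy", "radiotherapy", [1, 0])
    cat_row("event", "event", [1, 0])
    cont_row("time_months", "time_months")
    return pd.DataFrame(rows)
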