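"""Prognostic stratification: density quadrants, Kaplan-Meier curves,
k-sample log-rank (Mantel-Cox) test and Fisher's exact test.

Quadrants are defined by dual density cut-offs (defaults 533 G3 cells/mm^2
and 4133 Other cells/mm^2) with a uniform strict-greater positivity rule so
the four regions partition the density plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

log = logging.getLogger(__name__)

QUADRANTS = ("G3+/O-", "G3+/O+", "G3-/O-", "G3-/O+")
DEFAULT_CUTS = (533.0, 4133.0)


def assign_quadrant(dens_g3: float, dens_other: float, cuts=DEFAULT_CUTS) -> str:
    """Quadrant of a sample; positivity means strictly above the cut."""
    if dens_g3 < 0 or dens_other < 0:
        raise ValueError("densities must be >= 0")
    g3 = "G3+" if dens_g3 > cuts[0] else "G3-"
    o = "O+" if dens_other > cuts[1] else "O-"
    return f"{g3}/{o}"


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate over the distinct event times."""

    event_times: np.ndarray  # ascending, times with >= 1 event
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S at each event time (after the drop)
    n: int
    median: float | None  # days, None = not reached

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier fit; censored subjects at an event time stay at risk."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0 or 1")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    ev_times = np.unique(t[e == 1])
    n_at_risk = np.empty(len(ev_times), dtype=int)
    n_events = np.empty(len(ev_times), dtype=int)
    surv = np.empty(len(ev_times))
    s = 1.0
    for i, ti in enumerate(ev_times):
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & (e == 1)).sum())
        n_at_risk[i] = n_i
        n_events[i] = d_i
        s *= 1.0 - d_i / n_i
        surv[i] = s
    median = None
    below = np.nonzero(surv <= 0.5 + 1e-12)[0]
    if below.size:
        median = float(ev_times[below[0]])
    return KMCurve(ev_times, n_at_risk, n_events, surv, int(times.size), median)


def km_median(curve: KMCurve) -> float | None:
    """Smallest event time with S <= 0.5, or None when not reached."""
    return curve.median


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


def logrank(groups) -> LogRankResult:
    """k-sample log-rank test.

    ``groups`` is a list of (times, events) pairs.  Observed-minus-expected
    event counts are accumulated over the pooled distinct event times with
    the hypergeometric variance-covariance; ties are processed together at
    their shared time.
    """
    groups = [
        (np.asarray(t, dtype=float), np.asarray(e, dtype=int)) for t, e in groups
    ]
    if len(groups) < 2 or any(t.size == 0 for t, _ in groups):
        raise ValueError("need >= 2 non-empty groups")
    k = len(groups)
    all_t = np.concatenate([t for t, _ in groups])
    all_e = np.concatenate([e for _, e in groups])
    gid = np.concatenate([np.full(t.size, g) for g, (t, _) in enumerate(groups)])
    ev_times = np.unique(all_t[all_e == 1])
    if ev_times.size == 0:
        raise ValueError("no events in any group")
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for ti in ev_times:
        at_risk = all_t >= ti
        n = int(at_risk.sum())
        if n <= 1:
            continue
        d = int(((all_t == ti) & (all_e == 1)).sum())
        n_g = np.array([(at_risk & (gid == g)).sum() for g in range(k)], dtype=float)
        d_g = np.array(
            [((all_t == ti) & (all_e == 1) & (gid == g)).sum() for g in range(k)],
            dtype=float,
        )
        O += d_g
        E += d * n_g / n
        frac = n_g / n
        c = d * (n - d) / (n - 1)
        V += c * (np.diag(frac) - np.outer(frac, frac))
    z = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        chi2 = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return LogRankResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FisherResult:
    p: float
    method: str  # "exact" or "monte-carlo"
    se: float | None = None  # Monte-Carlo standard error


class _TooManyTables(Exception):
    pass


def _fisher_2x2(table: np.ndarray) -> float:
    """Two-sided p by probability-mass ordering (hypergeometric tails)."""
    a = int(table[0, 0])
    r1, r2 = int(table[0].sum()), int(table[1].sum())
    c1 = int(table[:, 0].sum())
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())


def _enumerate_rxc(table: np.ndarray, max_states: int = 20_000_000) -> float:
    """Exact r x c p-value by vectorized enumeration of all margin-fixed
    tables (probability-mass ordering)."""
    rowm = table.sum(axis=1).astype(int)
    colm = table.sum(axis=0).astype(int)
    n = int(table.sum())
    r, c = len(rowm), len(colm)
    logK = gammaln(rowm + 1).sum() + gammaln(colm + 1).sum() - gammaln(n + 1)
    obs_logp = logK - gammaln(table + 1).sum()

    rem = colm[None, :].astype(np.int64).copy()  # (S, c) column remainders
    lp = np.zeros(1)  # accumulated -sum(lgamma(x+1))
    lg = gammaln(np.arange(n + 2))
    for i in range(r - 1):
        rrem = np.full(rem.shape[0], rowm[i], dtype=np.int64)
        for j in range(c - 1):
            xmax = np.minimum(rrem, rem[:, j])
            counts = xmax + 1
            total = int(counts.sum())
            if total > max_states:
                raise _TooManyTables
            idx = np.repeat(np.arange(rem.shape[0]), counts)
            offs = np.concatenate(([0], np.cumsum(counts)[:-1]))
            x = np.arange(total) - np.repeat(offs, counts)
            rem = rem[idx]
            rrem = rrem[idx]
            lp = lp[idx]
            lp = lp - lg[x + 1]
            rem[:, j] = rem[:, j] - x
            rrem = rrem - x
        ok = rrem <= rem[:, c - 1]
        rem = rem[ok]
        rrem = rrem[ok]
        lp = lp[ok] - lg[rrem + 1]
        rem[:, c - 1] -= rrem
    # last row fully determined by column remainders
    lp = lp - lg[rem + 1].sum(axis=1) + logK
    return float(np.exp(lp[lp <= obs_logp + 1e-7]).sum())


def fisher_exact(
    table,
    *,
    mc_draws: int = 100_000,
    seed: int = 0,
    exact_total_limit: int = 200,
) -> FisherResult:
    """Two-sided Fisher's exact test for an r x c contingency table.

    2x2 tables use direct hypergeometric enumeration; larger tables with
    total <= ``exact_total_limit`` are enumerated exactly, otherwise a
    seeded Monte-Carlo p-value (Patefield sampling) with its standard error
    is returned.  Zero-margin rows/columns are dropped with a warning.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("table must be a non-negative 2-D integer array")
    if table.sum() <= 0:
        raise ValueError("table total must be > 0")
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        log.warning("dropping zero-margin rows/columns from Fisher table")
        table = table[keep_r][:, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return FisherResult(p=1.0, method="exact")
    if table.shape == (2, 2):
        return FisherResult(p=min(1.0, _fisher_2x2(table)), method="exact")
    if int(table.sum()) <= exact_total_limit:
        try:
            return FisherResult(p=min(1.0, _enumerate_rxc(table)), method="exact")
        except _TooManyTables:
            log.warning("enumeration too large; falling back to Monte-Carlo")
    rng = np.random.default_rng(seed)
    rowm = table.sum(axis=1)
    colm = table.sum(axis=0)
    lg_obs = -gammaln(table + 1).sum()
    sampler = stats.random_table(rowm, colm)
    hits = 0
    done = 0
    chunk = 20_000
    while done < mc_draws:
        m = min(chunk, mc_draws - done)
        draws = sampler.rvs(size=m, random_state=rng)
        lgs = -gammaln(draws + 1).sum(axis=(1, 2))
        hits += int((lgs <= lg_obs + 1e-7).sum())
        done += m
    p = (hits + 1) / (mc_draws + 1)
    se = float(np.sqrt(p * (1 - p) / mc_draws))
    return FisherResult(p=float(p), method="monte-carlo", se=se)


# ---------------------------------------------------------------------------
# Cohort analysis
# ---------------------------------------------------------------------------


def cohort_analysis(samples: pd.DataFrame, cuts=DEFAULT_CUTS, *, seed: int = 0) -> dict:
    """Full prognostic report for a cohort table.

    Expects columns sample_id, grade, dens_g3, dens_other, time_days,
    event.  Produces per-quadrant KM curves and medians, the k-sample
    log-rank test over populated quadrants, Fisher's exact test of the
    quadrant x grade table, and the density scatter summary.
    """
    df = samples.copy()
    df["quadrant"] = [
        assign_quadrant(g3, ot, cuts)
        for g3, ot in zip(df["dens_g3"], df["dens_other"])
    ]
    report: dict = {"cuts": {"g3": cuts[0], "other": cuts[1]}, "quadrants": {}}
    populated = []
    for q in QUADRANTS:
        sub = df[df["quadrant"] == q]
        entry: dict = {"n": int(len(sub)), "n_events": int(sub["event"].sum())}
        if len(sub):
            curve = km_fit(sub["time_days"].to_numpy(), sub["event"].to_numpy())
            entry["median_days"] = curve.median  # None = not reached
            entry["median_status"] = (
                "reached" if curve.median is not None
                else ("not reached" if curve.survival.size == 0 or curve.survival[-1] > 0.5
                      else "undetermined")
            )
            entry["km"] = {
                "time": curve.event_times.tolist(),
                "n_risk": curve.n_at_risk.tolist(),
                "n_event": curve.n_events.tolist(),
                "survival": curve.survival.tolist(),
            }
            populated.append(q)
        report["quadrants"][q] = entry

    overall = km_fit(df["time_days"].to_numpy(), df["event"].to_numpy())
    report["overall_median_days"] = overall.median

    if len(populated) >= 2:
        lr = logrank(
            [
                (
                    df.loc[df["quadrant"] == q, "time_days"].to_numpy(),
                    df.loc[df["quadrant"] == q, "event"].to_numpy(),
                )
                for q in populated
            ]
        )
        report["logrank"] = {"chi2": lr.chi2, "df": lr.df, "p": lr.p, "skipped": False}
    else:
        report["logrank"] = {"skipped": True, "reason": "<2 populated quadrants"}

    grades = sorted(df["grade"].unique())
    ctab = np.array(
        [
            [int(((df["quadrant"] == q) & (df["grade"] == g)).sum()) for g in grades]
            for q in QUADRANTS
        ]
    )
    report["contingency"] = {
        "rows": list(QUADRANTS),
        "cols": [int(g) for g in grades],
        "table": ctab.tolist(),
    }
    if len(populated) >= 2 and len(grades) >= 2:
        fr = fisher_exact(ctab, seed=seed)
        report["fisher"] = {"p": fr.p, "method": fr.method, "se": fr.se}
    else:
        report["fisher"] = {"skipped": True}

    report["scatter"] = [
        {
            "sample_id": row.sample_id,
            "dens_g3": float(row.dens_g3),
            "dens_other": float(row.dens_other),
            "quadrant": row.quadrant,
            "grade": int(row.grade),
            "event": int(row.event),
        }
        for row in df.itertuples()
    ]
    return report
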