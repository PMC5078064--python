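"""Survival and association statistics implemented from first principles.

The estimators here are the complete statistical toolkit used by the
splice-variant survival analysis: the Kaplan–Meier product-limit estimator
of the survival function under right-censoring, the k-sample log-rank
(Mantel–Cox) test with the standard finite-population tie correction,
Pearson correlation with the two-tailed t-transform p-value, and the
unpaired two-sample t-test (pooled-variance Student by default, Welch as
an option).

Only distribution tail functions are taken from :mod:`scipy.stats`; the
statistics themselves are computed here so they can be checked against
independent oracles (brute-force product-limit, permutation nulls,
textbook formulas) in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _spdist

__all__ = [
    "KMCurve",
    "LogRankResult",
    "PearsonResult",
    "TTestResult",
    "km_estimate",
    "logrank_test",
    "pairwise_logrank",
    "pearson",
    "unpaired_t",
]


def _as_time_event(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("need a non-empty 1-d array of times")
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and >= 0")
    if events is None:
        e = np.ones(t.shape, dtype=bool)
    else:
        e = np.asarray(events).astype(bool)
        if e.shape != t.shape:
            raise ValueError("times and events must have equal length")
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate evaluated at the distinct event times.

    ``survival[k]`` is S(t) just after ``times[k]``; the curve starts at 1
    before the first event. ``at_risk`` and ``n_events`` are the risk-set
    size and number of deaths at each event time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step-function value of the estimate at time ``t``."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    group_observed: dict = field(default_factory=dict)
    group_expected: dict = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"log-rank chi2={self.chi_square:.4g} df={self.df} "
            f"p={self.p_value:.4g}"
        )


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float


def km_estimate(times, events=None) -> KMCurve:
    """Kaplan–Meier product-limit estimate of the survival function.

    Parameters
    ----------
    times : array-like
        Follow-up times in days (>= 0).
    events : array-like of bool, optional
        True where death was observed; False marks right-censoring.
        Omitted means every record is an event. Individuals censored at an
        event time are counted in the risk set at that time (the standard
        convention).
    """
    t, e = _as_time_event(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]

    event_times = np.unique(t[e])
    n = t.size
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    s = 1.0
    for k, et in enumerate(event_times):
        nk = int(np.sum(t >= et))
        dk = int(np.sum(e & (t == et)))
        s *= 1.0 - dk / nk
        surv[k] = s
        at_risk[k] = nk
        n_events[k] = dk
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk, n_events=n_events)


def _logrank_arrays(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Observed/expected events per group and the Mantel–Cox chi-square.

    At each distinct event time the expected count per group is the
    hypergeometric mean d*n_j/n and the variance–covariance uses the
    finite-population tie correction (n-d)/(n-1), taken as 0 when n=1.
    The quadratic form drops the last group.
    """
    labels, gidx = np.unique(groups, return_inverse=True)
    k = labels.size
    event_times = np.unique(times[events])
    if event_times.size == 0:
        raise ValueError("no observed events: all records censored")

    observed = np.zeros(k)
    expected = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        risk = times >= et
        n = int(risk.sum())
        nj = np.bincount(gidx[risk], minlength=k).astype(float)
        dead = events & (times == et)
        d = int(dead.sum())
        dj = np.bincount(gidx[dead], minlength=k).astype(float)
        w = nj / n
        observed += dj
        expected += d * w
        corr = 0.0 if n <= 1 else d * (n - d) / (n - 1)
        V += corr * (np.diag(w) - np.outer(w, w))

    z = (observed - expected)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        chi2 = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    return chi2, observed, expected, labels


def logrank_test(
    group_times: Sequence, group_events: Sequence | None = None,
    *, labels: Sequence | None = None,
) -> LogRankResult:
    """k-sample log-rank (Mantel–Cox) test.

    Parameters
    ----------
    group_times : sequence of array-likes
        One array of follow-up times per group (>= 2 non-empty groups).
    group_events : sequence of array-likes, optional
        Matching event indicators; omitted means all events.
    labels : sequence, optional
        Group names for the observed/expected report.
    """
    if len(group_times) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if group_events is None:
        group_events = [None] * len(group_times)
    ts, es, gs = [], [], []
    names = list(labels) if labels is not None else list(range(len(group_times)))
    for name, gt, ge in zip(names, group_times, group_events):
        t, e = _as_time_event(gt, ge)
        ts.append(t)
        es.append(e)
        gs.append(np.full(t.size, str(name)))
    times = np.concatenate(ts)
    events = np.concatenate(es)
    groups = np.concatenate(gs)

    chi2, obs, exp, uniq = _logrank_arrays(times, events, groups)
    df = uniq.size - 1
    p = float(_spdist.chi2.sf(chi2, df))
    return LogRankResult(
        chi_square=chi2,
        df=df,
        p_value=p,
        group_observed={u: float(o) for u, o in zip(uniq, obs)},
        group_expected={u: float(x) for u, x in zip(uniq, exp)},
    )


def pairwise_logrank(
    group_times: dict, group_events: dict | None = None, *, holm: bool = False
) -> pd.DataFrame:
    """All pairwise two-group log-rank tests among named groups.

    p-values are unadjusted by default; ``holm=True`` adds a
    Holm step-down adjusted column.
    """
    names = list(group_times)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ev = None
            if group_events is not None:
                ev = [group_events[a], group_events[b]]
            res = logrank_test([group_times[a], group_times[b]], ev, labels=[a, b])
            rows.append({"group_a": a, "group_b": b,
                         "chi_square": res.chi_square, "p_value": res.p_value})
    out = pd.DataFrame(rows)
    if holm and len(out):
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    return out


def pearson(x, y) -> PearsonResult:
    """Sample Pearson correlation with two-tailed p from the t transform.

    p is computed from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom; |r| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in an input vector")
    r = float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _spdist.t.sf(abs(tstat), n - 2))
    return PearsonResult(r=r, p_value=p, n=n)


def unpaired_t(x, y, pooled: bool = True) -> TTestResult:
    """Unpaired two-sample t-test, two-tailed.

    ``pooled=True`` is the classic Student test with pooled variance;
    ``pooled=False`` is Welch's test with Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    diff = x.mean() - y.mean()
    if pooled:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    else:
        a, b = vx / nx, vy / ny
        se = np.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (nx - 1) + b**2 / (ny - 1))
    if se == 0:
        tstat = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        tstat = diff / se
    p = float(2.0 * _spdist.t.sf(abs(tstat), df)) if np.isfinite(tstat) else 0.0
    return TTestResult(t=float(tstat), df=float(df), p_value=p)
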