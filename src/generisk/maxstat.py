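"""Maximally selected log-rank statistics for survival cutpoint search.

For a continuous marker x and right-censored survival data, the maximally
selected rank statistic is

    M = max over candidate cutpoints mu of |z(mu)|,

where z(mu) is the standardized two-sample log-rank statistic comparing
patients with x > mu against x <= mu.  Candidate cutpoints are the distinct
observed marker values whose empirical quantile falls inside a window
[q_low, q_high] (0.10-0.90 by default), which keeps both groups away from
degenerate sizes and bounds the variance of the underlying process.

Because M is a maximum over many correlated statistics, its null
distribution is not standard normal.  ``maxstat_pvalue`` applies the
Brownian-bridge crossing-probability approximation of Lausen & Schumacher
(1992) for the supremum of the standardized process over the quantile
window; it is mildly conservative at typical cohort sizes.

``select_prognostic_probesets`` runs the scan for every probe of a cohort
and controls the false discovery rate across probes with
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateGroupError,
    DomainError,
    NoEventsError,
    NoValidCutpointError,
)

__all__ = [
    "MaxstatResult",
    "SelectionTable",
    "standardized_logrank_stat",
    "maxstat_scan",
    "maxstat_pvalue",
    "benjamini_hochberg",
    "select_prognostic_probesets",
]

DEFAULT_QUANTILE_WINDOW = (0.10, 0.90)


@dataclass
class MaxstatResult:
    """Outcome of a maximally-selected log-rank scan for one marker."""

    probe_id: str
    cutpoint: float
    max_stat: float
    p_raw: float
    candidate_count: int
    quantile_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        if self.max_stat < 0:
            raise DomainError("max_stat must be non-negative")
        if not 0.0 <= self.p_raw <= 1.0:
            raise DomainError("p_raw must lie in [0, 1]")


@dataclass
class SelectionTable:
    """Per-probe maxstat results with BH-adjusted p-values.

    ``rows`` preserves the probe order of the input matrix; ``p_adj`` is
    aligned with ``rows``; ``selected`` flags probes with p_adj < alpha
    (strict inequality).
    """

    rows: list[MaxstatResult]
    p_adj: np.ndarray
    alpha: float
    skipped: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[MaxstatResult]:
        return [r for r, p in zip(self.rows, self.p_adj) if p < self.alpha]

    @property
    def selected_ids(self) -> list[str]:
        return [r.probe_id for r in self.selected]


def _prepare_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape or time.ndim != 1:
        raise DomainError("time and event must be 1-D arrays of equal length")
    if event.sum() == 0:
        raise NoEventsError("no events observed")
    return time, event


def _logrank_z_many(time: np.ndarray, event: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Signed standardized log-rank statistics for many dichotomies at once.

    ``groups`` is a (k, n) boolean matrix; row g defines group 1.  Returns a
    length-k vector of z = (O1 - E1) / sqrt(V) accumulated over distinct
    event times with the hypergeometric variance at ties.  Rows whose group
    is empty or exhaustive yield NaN.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    g = groups[:, order].astype(np.float64)
    n = t.size

    event_times = np.unique(t[e == 1])
    # block boundaries for each distinct event time
    starts = np.searchsorted(t, event_times, side="left")
    ends = np.searchsorted(t, event_times, side="right")

    r = (n - starts).astype(np.float64)  # total at risk
    # events at each distinct time (all groups)
    ecum = np.concatenate([[0.0], np.cumsum(e)])
    d = ecum[ends] - ecum[starts]

    # at-risk and event counts in group 1, per candidate (k, m)
    g_tail = np.cumsum(g[:, ::-1], axis=1)[:, ::-1]
    r1 = np.concatenate([g_tail, np.zeros((g.shape[0], 1))], axis=1)[:, starts]
    ge_cum = np.concatenate(
        [np.zeros((g.shape[0], 1)), np.cumsum(g * e, axis=1)], axis=1
    )
    d1 = ge_cum[:, ends] - ge_cum[:, starts]

    frac = r1 / r
    o_minus_e = (d1 - d * frac).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * frac * (1.0 - frac) * np.where(r > 1, (r - d) / (r - 1), 0.0)
    var = v.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = o_minus_e / np.sqrt(var)
    z[var <= 0] = np.nan
    return z


def standardized_logrank_stat(time, event, group) -> float:
    """Signed standardized log-rank statistic (O - E)/sqrt(V) for group 1.

    Accumulates observed minus expected events and the hypergeometric
    variance over distinct event times; its square is the two-sample
    log-rank chi-square.  A positive value means group 1 experienced more
    events than expected, i.e. worse survival.
    """
    time, event = _prepare_survival(time, event)
    group = np.asarray(group).astype(bool)
    if group.shape != time.shape:
        raise DomainError("group must align with time/event")
    if group.all() or not group.any():
        raise DegenerateGroupError("both groups must be non-empty")
    z = _logrank_z_many(time, event, group[None, :])[0]
    if np.isnan(z):
        raise DegenerateGroupError("log-rank variance is zero for this split")
    return float(z)


def _candidate_cutpoints(values: np.ndarray, q_low: float, q_high: float) -> np.ndarray:
    """Distinct observed values whose empirical quantile (fraction of
    observations <= value) lies in [q_low, q_high]."""
    distinct = np.unique(values)
    frac_le = np.searchsorted(np.sort(values), distinct, side="right") / values.size
    keep = (frac_le >= q_low) & (frac_le <= q_high)
    return distinct[keep]


def maxstat_scan(values, time, event, q_low: float = 0.10, q_high: float = 0.90,
                 probe_id: str = "") -> MaxstatResult:
    """Find the cutpoint maximizing |standardized log-rank| for one marker.

    Every distinct observed value with empirical quantile in
    [q_low, q_high] is tried as a dichotomizing cutpoint (group 1: value
    strictly greater).  Ties in the maximum are broken toward the smallest
    cutpoint.  The returned p-value is the Lausen-Schumacher approximation
    for the maximally selected statistic over the window.
    """
    _validate_window(q_low, q_high)
    values = np.asarray(values, dtype=float)
    time, event = _prepare_survival(time, event)
    if values.shape != time.shape:
        raise DomainError("values must align with time/event")

    candidates = _candidate_cutpoints(values, q_low, q_high)
    if candidates.size == 0 or np.unique(values).size < 2:
        raise NoValidCutpointError(
            f"no admissible cutpoint for probe {probe_id!r} "
            f"(distinct values within quantile window: {candidates.size})"
        )
    groups = values[None, :] > candidates[:, None]
    z = _logrank_z_many(time, event, groups)
    absz = np.abs(z)
    absz[np.isnan(absz)] = -np.inf
    if not np.isfinite(absz).any():
        raise NoValidCutpointError(
            f"all candidate splits degenerate for probe {probe_id!r}"
        )
    best = int(np.argmax(absz))  # argmax returns the first = smallest cutpoint
    m = float(absz[best])
    return MaxstatResult(
        probe_id=probe_id,
        cutpoint=float(candidates[best]),
        max_stat=m,
        p_raw=maxstat_pvalue(m, q_low, q_high),
        candidate_count=int(candidates.size),
        quantile_bounds=(q_low, q_high),
    )


def _validate_window(q_low: float, q_high: float) -> None:
    if not (0.0 < q_low < q_high < 1.0):
        raise DomainError(f"invalid quantile window ({q_low}, {q_high})")


def maxstat_pvalue(m: float, q_low: float = 0.10, q_high: float = 0.90) -> float:
    """Approximate P(sup |standardized log-rank process| > m) on the window.

    Uses the Brownian-bridge crossing bound of Lausen & Schumacher (1992):

        p ~= phi(m) * (m - 1/m) * log(q_high(1-q_low) / (q_low(1-q_high)))
             + 4 * phi(m) / m.

    The expansion is accurate for moderately large m but degenerates for
    small m (it can even turn negative), so the result is floored at the
    pointwise two-sided normal tail 2*(1 - Phi(m)) -- a valid lower bound,
    since the supremum dominates any single standardized statistic -- and
    capped at 1.  Monotone decreasing in m and increasing in the window
    width.
    """
    _validate_window(q_low, q_high)
    if m < 0:
        raise DomainError("statistic must be non-negative")
    if m == 0.0:
        return 1.0
    log_odds = np.log(q_high * (1.0 - q_low) / (q_low * (1.0 - q_high)))
    phi = stats.norm.pdf(m)
    p = phi * (m - 1.0 / m) * log_odds + 4.0 * phi / m
    p = max(p, 2.0 * stats.norm.sf(m))
    return float(min(1.0, p))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns adjusted p-values in the input order: sort ascending, multiply
    p_(i) by m/i, enforce monotonicity by a cumulative minimum from the
    largest rank, clip at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def select_prognostic_probesets(cohort, alpha: float = 0.05,
                                q_low: float = 0.10, q_high: float = 0.90) -> SelectionTable:
    """Genome-scale maxstat screen with BH correction across probes.

    Runs ``maxstat_scan`` for every probe of an aligned cohort, adjusts the
    raw p-values with Benjamini-Hochberg and flags probes with adjusted
    p < alpha.  Probes without an admissible cutpoint are skipped with a
    warning entry rather than failing the screen.
    """
    _validate_window(q_low, q_high)
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must lie in (0, 1)")
    expr = cohort.expression
    time = cohort.survival.time
    event = cohort.survival.event
    rows: list[MaxstatResult] = []
    skipped: list[str] = []
    for i, probe in enumerate(expr.probe_ids):
        try:
            rows.append(
                maxstat_scan(expr.values[i], time, event, q_low, q_high, probe_id=probe)
            )
        except NoValidCutpointError:
            skipped.append(probe)
    if not rows:
        raise NoValidCutpointError("no probe produced an admissible cutpoint")
    p_adj = benjamini_hochberg([r.p_raw for r in rows])
    return SelectionTable(rows=rows, p_adj=p_adj, alpha=alpha, skipped=skipped)
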