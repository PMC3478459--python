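"""Kaplan-Meier estimation, log-rank tests, Cox PH fits and group-wise
score comparisons.

Estimation is delegated to lifelines where it provides the standard tool
(product-limit curves, Efron-tie Cox fits, k-sample log-rank); a compact
Newton-Raphson fit on the Breslow partial likelihood is provided for
tie-handling cross-checks, since lifelines implements Efron ties only.
Medians follow the convention: median = smallest event time t with
S(t) <= 0.5, and "not reached" (``None``) if the curve never drops that
far within follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import (
    ConstantCovariateError,
    ConvergenceError,
    DegenerateGroupError,
    EmptyCohortError,
    NoEventsError,
)

__all__ = [
    "KMCurve",
    "CoxFit",
    "GroupComparison",
    "NOT_REACHED",
    "km_estimate",
    "logrank_test",
    "cox_ph_fit",
    "compare_score_across_groups",
    "format_median",
]

#: Sentinel used in all text reports for an undefined (censored) median.
NOT_REACHED = "not reached"


@dataclass
class KMCurve:
    """Product-limit survival curve with at-risk counts and median."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return self.median is not None


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    names: list[str]
    beta: np.ndarray
    hazard_ratio: np.ndarray
    se: np.ndarray
    p: np.ndarray
    log_likelihood: float
    converged: bool
    ties: str

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "HR": self.hazard_ratio,
                "se": self.se,
                "p": self.p,
            },
            index=self.names,
        )


@dataclass
class GroupComparison:
    """One group's score distribution against all remaining patients."""

    group: str
    n: int
    direction: str | None  # "higher" / "lower" relative to the rest
    p: float | None  # None when the group is too small to test


def format_median(median: float | None, precision: int = 1) -> str:
    return NOT_REACHED if median is None else f"{median:.{precision}f}"


def _as_survival_arrays(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    return time, event


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    time, event = _as_survival_arrays(time, event)
    if time.size == 0:
        raise EmptyCohortError("cannot estimate a survival curve for 0 patients")
    kmf = KaplanMeierFitter().fit(time, event)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    below = surv <= 0.5
    median = float(grid[below][0]) if below.any() else None
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        median=median,
        n=int(time.size),
        n_events=int(event.sum()),
    )


def logrank_test(time, event, labels) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (chi2, df, p).

    For two groups the chi-square equals the square of the standardized
    two-sample log-rank statistic.
    """
    time, event = _as_survival_arrays(time, event)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2 or (counts == 0).any():
        raise DegenerateGroupError("log-rank requires >= 2 non-empty groups")
    if event.sum() == 0:
        raise NoEventsError("log-rank requires at least one event")
    res = multivariate_logrank_test(time, labels, event)
    return float(res.test_statistic), int(groups.size - 1), float(res.p_value)


def _breslow_cox(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                 max_iter: int = 50, tol: float = 1e-9):
    """Newton-Raphson maximum partial likelihood with Breslow tie handling."""
    order = np.argsort(-time, kind="stable")  # decreasing time: risk sets by prefix
    x = x[order]
    t = time[order]
    e = event[order]
    n, p = x.shape
    beta = np.zeros(p)
    ll = -np.inf
    for _ in range(max_iter):
        eta = x @ beta
        w = np.exp(eta)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w[:, None] * x, axis=0)
        s2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)
        # risk set of an event at t_i = all with time >= t_i = prefix through
        # the last index sharing t_i (ties enter each other's risk sets)
        last = np.searchsorted(-t, -t, side="right") - 1
        ev = e == 1
        idx = last[ev]
        ll_new = float(eta[ev].sum() - np.log(s0[idx]).sum())
        grad = x[ev].sum(axis=0) - (s1[idx] / s0[idx, None]).sum(axis=0)
        mu = s1[idx] / s0[idx, None]
        hess = -(
            (s2[idx] / s0[idx, None, None])
            - mu[:, :, None] * mu[:, None, :]
        ).sum(axis=0)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        beta = beta - step
        if abs(ll_new - ll) < tol:
            ll = ll_new
            break
        ll = ll_new
    else:
        raise ConvergenceError("Breslow Cox fit did not converge")
    # recompute information at the optimum for standard errors
    eta = x @ beta
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * x, axis=0)
    s2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)
    idx = (np.searchsorted(-t, -t, side="right") - 1)[e == 1]
    mu = s1[idx] / s0[idx, None]
    info = ((s2[idx] / s0[idx, None, None]) - mu[:, :, None] * mu[:, None, :]).sum(axis=0)
    cov = np.linalg.inv(info)
    return beta, np.sqrt(np.diag(cov)), ll


def cox_ph_fit(covariates, time, event, ties: str = "efron") -> CoxFit:
    """Cox proportional-hazards fit by maximum partial likelihood.

    ``covariates`` is a patient x covariate table (DataFrame or 2-D array);
    any covariate mix is accepted (binary risk-group labels, dichotomized
    gene indicators, external continuous scores).  Efron tie handling is
    the default; ``ties="breslow"`` uses the in-package Newton fit.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    time, event = _as_survival_arrays(time, event)
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i}" for i in range(x.shape[1])]
    if x.shape[0] != time.size:
        raise ValueError("covariates must align with time/event")
    if event.sum() == 0:
        raise NoEventsError("Cox fit requires at least one event")
    const = x.std(axis=0) == 0
    if const.any():
        raise ConstantCovariateError(
            f"constant covariates: {[n for n, c in zip(names, const) if c]}"
        )
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more patients than covariates")

    if ties == "breslow":
        beta, se, ll = _breslow_cox(x, time, event)
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return CoxFit(names, beta, np.exp(beta), se, p,
                      float(ll), True, ties)

    df = pd.DataFrame(x, columns=names)
    df["_time"] = time
    df["_event"] = event
    fitter = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fitter.fit(df, duration_col="_time", event_col="_event")
        except Exception as exc:
            raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    beta = fitter.params_.to_numpy(dtype=float)
    se = fitter.standard_errors_.to_numpy(dtype=float)
    p = fitter.summary["p"].to_numpy(dtype=float)
    return CoxFit(
        names=names,
        beta=beta,
        hazard_ratio=np.exp(beta),
        se=se,
        p=p,
        log_likelihood=float(fitter.log_likelihood_),
        converged=True,
        ties=ties,
    )


def compare_score_across_groups(scores, group_labels, min_size: int = 3,
                                alpha: float = 0.05) -> list[GroupComparison]:
    """Compare each group's score distribution against all other patients.

    Two-sided Wilcoxon rank-sum (Mann-Whitney) per group; groups smaller
    than ``min_size`` are reported descriptively with ``p=None``.  The
    direction is "higher"/"lower" by comparison of medians (rank-sum U as
    the tie-break).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(group_labels)
    if np.unique(labels).size < 2:
        raise DegenerateGroupError("need >= 2 distinct groups to compare")
    out: list[GroupComparison] = []
    for g in np.unique(labels):
        mask = labels == g
        n_g = int(mask.sum())
        inside, outside = scores[mask], scores[~mask]
        if n_g < min_size or outside.size < min_size:
            out.append(GroupComparison(str(g), n_g, None, None))
            continue
        u, p = stats.mannwhitneyu(inside, outside, alternative="two-sided")
        med_in, med_out = np.median(inside), np.median(outside)
        if med_in != med_out:
            direction = "higher" if med_in > med_out else "lower"
        else:
            direction = "higher" if u > inside.size * outside.size / 2 else "lower"
        out.append(GroupComparison(str(g), n_g, direction, float(p)))
    return out
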