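"""Gene-expression-based risk score: +/- beta sums over dichotomized probes.

For a set of prognostic probes, each with a survival-optimal cutpoint c_i
and a univariate Cox coefficient beta_i for the dichotomized indicator
1{expression > c_i}, a patient's score is

    S_j = sum_i s_ij * beta_i,   s_ij = +1 if e_ij > c_i else -1,

so every adverse probe above its cutpoint pushes the patient toward the
high-risk end.  The high/low threshold tau is the score value maximizing
the absolute standardized log-rank statistic between {S <= tau} and
{S > tau} on the training cohort; the proportion of training patients
above tau (p_high) is stored so the model can be transferred to a cohort
measured on a different platform by proportion rather than by raw score
value.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .errors import (
    DegenerateGroupError,
    MissingProbeError,
    NoEventsError,
    NoValidCutpointError,
    SeparationError,
)
from .maxstat import SelectionTable, _logrank_z_many
from .survival import km_estimate, logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "ProbePrognostic",
    "RiskScoreModel",
    "ScoredCohort",
    "ValidationReport",
    "fit_probe_beta",
    "compute_scores",
    "optimize_score_threshold",
    "classify_patients",
    "apply_model",
    "fit_risk_score_model",
    "save_model",
    "load_model",
]

HIGH, LOW = "high", "low"


@dataclass
class ProbePrognostic:
    """One probe's fitted selection and scoring parameters."""

    probe_id: str
    gene_symbol: str
    cutpoint: float
    beta: float
    hazard_ratio: float
    p_raw: float | None = None
    p_adj: float | None = None
    separation_flagged: bool = False
    check_consistency: bool = True

    def __post_init__(self) -> None:
        if self.check_consistency and self.beta is not None:
            if self.hazard_ratio is None:
                self.hazard_ratio = math.exp(self.beta)
            elif not math.isclose(self.hazard_ratio, math.exp(self.beta),
                                  rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    f"{self.probe_id}: hazard_ratio {self.hazard_ratio} != "
                    f"exp(beta) {math.exp(self.beta)}"
                )


@dataclass
class RiskScoreModel:
    """A frozen risk-score model: probes, threshold and training proportion."""

    probes: list[ProbePrognostic]
    threshold: float
    p_high: float
    transfer_mode: str = "by_proportion"

    def __post_init__(self) -> None:
        if self.transfer_mode not in ("by_value", "by_proportion"):
            raise ValueError(f"unknown transfer_mode {self.transfer_mode!r}")
        if not 0.0 < self.p_high < 1.0:
            raise ValueError("p_high must lie strictly inside (0, 1)")
        # tau is an observed score with {S > tau} non-empty, so it can touch
        # the lower bound (an all-below patient) but never the upper one
        bound = sum(abs(p.beta) for p in self.probes)
        if not -bound <= self.threshold < bound:
            raise ValueError(
                f"threshold {self.threshold} outside achievable score range "
                f"(-{bound}, {bound})"
            )

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def score_bound(self) -> float:
        return sum(abs(p.beta) for p in self.probes)


@dataclass
class ScoredCohort:
    """Per-patient scores and high/low risk labels."""

    patient_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray  # "high" / "low"

    @property
    def high_fraction(self) -> float:
        return float(np.mean(self.labels == HIGH))


@dataclass
class ValidationReport:
    """Outcome of transferring a frozen model to a cohort."""

    scored: ScoredCohort
    logrank_chi2: float
    logrank_p: float
    km_by_group: dict
    median_by_group: dict
    dropped_probes: list[str] = field(default_factory=list)


def fit_probe_beta(values, cutpoint, time, event,
                   beta_cap: float = 10.0) -> tuple[float, float]:
    """Univariate Cox coefficient for the dichotomy 1{value > cutpoint}.

    Returns (beta, HR = exp(beta)).  When the likelihood is monotone (all
    events on one side of the cut) the coefficient diverges; the probe is
    flagged by raising :class:`SeparationError`, and callers may cap beta
    at ``+/-beta_cap`` via :func:`capped_beta`.
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = values > cutpoint
    if group.all() or not group.any():
        raise DegenerateGroupError("cutpoint does not split the cohort")
    if event.sum() == 0:
        raise NoEventsError("no events observed")
    if event[group].sum() == 0 or event[~group].sum() == 0:
        raise SeparationError(
            "all events fall on one side of the cutpoint; beta is unbounded "
            f"(cap at +/-{beta_cap})"
        )
    df = pd.DataFrame({"x": group.astype(float), "_t": time, "_e": event})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = CoxPHFitter().fit(df, duration_col="_t", event_col="_e")
    beta = float(fit.params_.iloc[0])
    if abs(beta) > beta_cap:
        raise SeparationError(f"|beta| = {abs(beta):.2f} exceeds cap {beta_cap}")
    return beta, float(np.exp(beta))


def capped_beta(sign: float, beta_cap: float = 10.0) -> tuple[float, float]:
    """Capped coefficient for a separation-flagged probe."""
    b = math.copysign(beta_cap, sign)
    return b, math.exp(b)


def compute_scores(expr, probes: list[ProbePrognostic]) -> np.ndarray:
    """Per-patient score S_j = sum_i (+/-1) * beta_i.

    A probe contributes +beta_i when the patient's signal is strictly above
    the probe's cutpoint and -beta_i otherwise (equality counts as below).
    Independent of probe order.
    """
    missing = [p.probe_id for p in probes if p.probe_id not in expr.probe_ids]
    if missing:
        raise MissingProbeError(missing)
    scores = np.zeros(len(expr.patient_ids))
    for p in probes:
        sign = np.where(expr.probe_values(p.probe_id) > p.cutpoint, 1.0, -1.0)
        scores = scores + sign * p.beta
    return scores


def optimize_score_threshold(scores, time, event) -> tuple[float, float]:
    """Survival-difference-maximizing score threshold.

    Every distinct observed score (with both resulting groups non-empty) is
    tried as tau; the winner maximizes the absolute standardized log-rank
    statistic between {S <= tau} and {S > tau}.  Exact ties in the maximum
    are broken toward the more balanced split, then the smaller tau.
    Returns (tau, p_high) where p_high is the fraction of patients above
    tau.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise NoEventsError("no events observed")
    distinct = np.unique(scores)
    candidates = distinct[:-1]  # the maximum would leave {S > tau} empty
    if candidates.size == 0:
        raise NoValidCutpointError("all scores identical; no threshold exists")
    groups = scores[None, :] > candidates[:, None]
    z = _logrank_z_many(time, event, groups)
    absz = np.abs(z)
    absz[np.isnan(absz)] = -np.inf
    if not np.isfinite(absz).any():
        raise NoValidCutpointError("every candidate split is degenerate")
    best = absz.max()
    tied = np.flatnonzero(absz == best)
    if tied.size > 1:
        n = scores.size
        balance = np.abs(groups[tied].sum(axis=1) / n - 0.5)
        tied = tied[balance == balance.min()]
    tau = float(candidates[tied[0]])  # candidates ascending -> smallest tau
    p_high = float(np.mean(scores > tau))
    return tau, p_high


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def classify_patients(scores, patient_ids, model: RiskScoreModel) -> ScoredCohort:
    """Label patients high/low risk under the model's transfer mode.

    by_value: high iff S > tau.  by_proportion: the round-half-up top
    ``p_high`` fraction by score is high, descending score with stable
    patient order at boundary ties.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    labels = np.full(n, LOW, dtype=object)
    if model.transfer_mode == "by_value":
        labels[scores > model.threshold] = HIGH
    else:
        n_high = min(n, _round_half_up(model.p_high * n))
        order = np.argsort(-scores, kind="stable")
        labels[order[:n_high]] = HIGH
    return ScoredCohort(list(patient_ids), scores, np.asarray(labels, dtype=object))


def apply_model(model: RiskScoreModel, cohort, on_missing: str = "error") -> ValidationReport:
    """Score an independent cohort with FROZEN training parameters.

    Cutpoints, betas, tau and p_high all come from the training fit; the
    validation data are never refitted.  ``on_missing="drop"`` removes
    model probes absent from the validation matrix (logged prominently; the
    remaining betas are used as-is so the score simply spans a narrower
    range).  Returns per-patient labels, the two-group log-rank test and
    per-group Kaplan-Meier summaries.
    """
    if on_missing not in ("error", "drop"):
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    present = set(cohort.expression.probe_ids)
    missing = [p.probe_id for p in model.probes if p.probe_id not in present]
    probes = model.probes
    if missing:
        if on_missing == "error":
            raise MissingProbeError(missing)
        logger.warning(
            "apply_model: dropping %d of %d model probes absent from the "
            "cohort: %s", len(missing), len(model.probes), missing,
        )
        probes = [p for p in model.probes if p.probe_id in present]
        if not probes:
            raise MissingProbeError(missing)
    scores = compute_scores(cohort.expression, probes)
    scored = classify_patients(scores, cohort.patient_ids, model)
    time, event = cohort.survival.time, cohort.survival.event
    groups = np.unique(scored.labels)
    if groups.size == 2:
        chi2, _, p = logrank_test(time, event, scored.labels)
    else:  # a one-group classification carries no survival contrast
        chi2, p = float("nan"), float("nan")
    km, medians = {}, {}
    for g in groups:
        mask = scored.labels == g
        km[str(g)] = km_estimate(time[mask], event[mask])
        medians[str(g)] = km[str(g)].median
    return ValidationReport(
        scored=scored,
        logrank_chi2=chi2,
        logrank_p=p,
        km_by_group=km,
        median_by_group=medians,
        dropped_probes=missing if on_missing == "drop" else [],
    )


def fit_risk_score_model(cohort, selection: SelectionTable,
                         transfer_mode: str = "by_proportion",
                         beta_cap: float = 10.0) -> RiskScoreModel:
    """Build a risk-score model from a cohort and its maxstat screen.

    Fits the univariate Cox beta for every selected probe at its maxstat
    cutpoint (separation-flagged probes get a capped beta), computes
    training scores and optimizes the threshold.
    """
    probes: list[ProbePrognostic] = []
    time, event = cohort.survival.time, cohort.survival.event
    adj = {r.probe_id: p for r, p in zip(selection.rows, selection.p_adj)}
    for res in selection.selected:
        values = cohort.expression.probe_values(res.probe_id)
        flagged = False
        try:
            beta, hr = fit_probe_beta(values, res.cutpoint, time, event, beta_cap)
        except SeparationError:
            above = values > res.cutpoint
            sign = 1.0 if event[above].sum() > 0 else -1.0
            beta, hr = capped_beta(sign, beta_cap)
            flagged = True
            logger.warning("probe %s: monotone likelihood, beta capped at %.1f",
                           res.probe_id, beta)
        probes.append(
            ProbePrognostic(
                probe_id=res.probe_id,
                gene_symbol=cohort.expression.symbol_for(res.probe_id),
                cutpoint=res.cutpoint,
                beta=beta,
                hazard_ratio=hr,
                p_raw=res.p_raw,
                p_adj=float(adj[res.probe_id]),
                separation_flagged=flagged,
            )
        )
    if not probes:
        raise NoValidCutpointError("no probes selected; cannot build a score")
    scores = compute_scores(cohort.expression, probes)
    tau, p_high = optimize_score_threshold(scores, time, event)
    return RiskScoreModel(probes=probes, threshold=tau, p_high=p_high,
                          transfer_mode=transfer_mode)


def save_model(model: RiskScoreModel, path) -> None:
    """Serialize a model to JSON; floats round-trip exactly."""
    payload = {
        "threshold": model.threshold,
        "p_high": model.p_high,
        "transfer_mode": model.transfer_mode,
        "probes": [
            {
                "probe_id": p.probe_id,
                "gene_symbol": p.gene_symbol,
                "cutpoint": p.cutpoint,
                "beta": p.beta,
                "hazard_ratio": p.hazard_ratio,
                "p_raw": p.p_raw,
                "p_adj": p.p_adj,
                "separation_flagged": p.separation_flagged,
            }
            for p in model.probes
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> RiskScoreModel:
    with open(path) as fh:
        payload = json.load(fh)
    probes = [ProbePrognostic(**entry) for entry in payload["probes"]]
    return RiskScoreModel(
        probes=probes,
        threshold=payload["threshold"],
        p_high=payload["p_high"],
        transfer_mode=payload["transfer_mode"],
    )
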