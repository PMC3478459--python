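"""Single-gene dichotomies and combined score x gene stratification.

Single adverse genes (EVI1, BAALC, ERG, MN1 in the AML setting) are
dichotomized at their own survival-optimal cutpoints and combined with the
risk-score label into a three-group stratification:

    G1  score low (regardless of gene status)
    G2  score high, gene low
    G3  score high, gene high

The four-way score x gene table is also computed; the three-group view is
its merge of the two score-low cells, which is the clinically reported
partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyCohortError, MissingProbeError
from .maxstat import MaxstatResult, maxstat_scan
from .score import HIGH, ScoredCohort, fit_probe_beta
from .survival import KMCurve, km_estimate, logrank_test

__all__ = [
    "GeneDichotomy",
    "StratificationResult",
    "gene_maxstat_dichotomize",
    "three_group_stratify",
    "GROUP_SCORE_LOW",
    "GROUP_HIGH_GENE_LOW",
    "GROUP_HIGH_GENE_HIGH",
]

GROUP_SCORE_LOW = "low_risk"
GROUP_HIGH_GENE_LOW = "high_risk_gene_low"
GROUP_HIGH_GENE_HIGH = "high_risk_gene_high"


@dataclass
class GeneDichotomy:
    """A single gene dichotomized at its maxstat cutpoint."""

    gene: str
    probe_id: str
    cutpoint: float
    patient_ids: list[str]
    labels: np.ndarray  # "high" / "low"
    maxstat: MaxstatResult
    beta: float
    hazard_ratio: float


@dataclass
class StratificationResult:
    """Three-group partition with per-group survival summaries."""

    patient_ids: list[str]
    groups: np.ndarray
    fractions: dict[str, float]
    sizes: dict[str, int]
    km_by_group: dict[str, KMCurve]
    median_by_group: dict[str, float | None]
    logrank_chi2: float
    logrank_df: int
    logrank_p: float
    four_way_sizes: dict[str, int] | None = None


def gene_maxstat_dichotomize(cohort, gene_probe: str, gene_name: str | None = None,
                             q_low: float = 0.10, q_high: float = 0.90) -> GeneDichotomy:
    """Dichotomize one probe at its survival-optimal cutpoint.

    Runs the maxstat scan on the single probe, labels patients high/low by
    the strict-greater convention and reports the univariate Cox hazard
    ratio of the dichotomy.
    """
    if gene_probe not in cohort.expression.probe_ids:
        raise MissingProbeError([gene_probe])
    values = cohort.expression.probe_values(gene_probe)
    time, event = cohort.survival.time, cohort.survival.event
    result = maxstat_scan(values, time, event, q_low, q_high, probe_id=gene_probe)
    beta, hr = fit_probe_beta(values, result.cutpoint, time, event)
    labels = np.where(values > result.cutpoint, "high", "low").astype(object)
    return GeneDichotomy(
        gene=gene_name or cohort.expression.symbol_for(gene_probe),
        probe_id=gene_probe,
        cutpoint=result.cutpoint,
        patient_ids=list(cohort.patient_ids),
        labels=labels,
        maxstat=result,
        beta=beta,
        hazard_ratio=hr,
    )


def three_group_stratify(scored: ScoredCohort, gene: GeneDichotomy,
                         surv) -> StratificationResult:
    """Combine risk-score and gene labels into the three-group partition.

    Score-low patients form G1 regardless of gene status; score-high
    patients split into G2 (gene low) and G3 (gene high).  Structurally
    empty groups are reported with size 0.  The overall contrast is the
    k-sample log-rank over the non-empty groups.
    """
    if scored.patient_ids != gene.patient_ids or scored.patient_ids != surv.patient_ids:
        raise EmptyCohortError(
            "score, gene and survival components must cover identical patients "
            "in identical order"
        )
    n = len(scored.patient_ids)
    if n == 0:
        raise EmptyCohortError("empty cohort")
    score_high = scored.labels == HIGH
    gene_high = gene.labels == "high"
    groups = np.where(
        ~score_high,
        GROUP_SCORE_LOW,
        np.where(gene_high, GROUP_HIGH_GENE_HIGH, GROUP_HIGH_GENE_LOW),
    ).astype(object)

    all_groups = [GROUP_SCORE_LOW, GROUP_HIGH_GENE_LOW, GROUP_HIGH_GENE_HIGH]
    sizes = {g: int((groups == g).sum()) for g in all_groups}
    fractions = {g: sizes[g] / n for g in all_groups}
    km, medians = {}, {}
    time, event = surv.time, surv.event
    for g in all_groups:
        mask = groups == g
        if mask.any():
            km[g] = km_estimate(time[mask], event[mask])
            medians[g] = km[g].median
    non_empty = [g for g in all_groups if sizes[g] > 0]
    if len(non_empty) >= 2:
        chi2, df, p = logrank_test(time, event, groups)
    else:
        chi2, df, p = float("nan"), 0, float("nan")
    four_way = {
        "score_low_gene_low": int((~score_high & ~gene_high).sum()),
        "score_low_gene_high": int((~score_high & gene_high).sum()),
        "score_high_gene_low": int((score_high & ~gene_high).sum()),
        "score_high_gene_high": int((score_high & gene_high).sum()),
    }
    return StratificationResult(
        patient_ids=list(scored.patient_ids),
        groups=groups,
        fractions=fractions,
        sizes=sizes,
        km_by_group=km,
        median_by_group=medians,
        logrank_chi2=chi2,
        logrank_df=df,
        logrank_p=p,
        four_way_sizes=four_way,
    )
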