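"""End-to-end orchestration: select -> score -> threshold -> validate -> stratify.

``run_pipeline`` executes the whole analysis from a single
:class:`PipelineConfig`, writes the report bundle (selection table, Cox
table, per-patient scores, stratification tables, KM curves, a
score-ordered expression heatmap and a machine-readable manifest) and
returns the in-memory results.  Input cohorts come either from files or
from the synthetic generator (``simulate=True``).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from . import __version__
from .data import (
    CohortDataset,
    align_cohort,
    read_clinical_table,
    read_expression_matrix,
    write_selection_table,
)
from .errors import ConfigError, GeneriskError
from .maxstat import select_prognostic_probesets
from .score import apply_model, classify_patients, compute_scores, fit_risk_score_model, save_model
from .simulate import GeneSpec, SimulationConfig, generate_training_validation_pair
from .stratify import gene_maxstat_dichotomize, three_group_stratify
from .survival import cox_ph_fit, format_median, km_estimate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "generisk_run"
    simulate: bool = False
    seed: int | None = None
    # file inputs (ignored when simulate=True)
    training_expression: str | None = None
    training_clinical: str | None = None
    validation_expression: str | None = None
    validation_clinical: str | None = None
    patient_col: str = "patient_id"
    time_col: str = "os_months"
    event_col: str = "os_event"
    decimal: str = "."
    # analysis parameters
    alpha: float = 0.05
    q_low: float = 0.10
    q_high: float = 0.90
    transfer_mode: str = "by_proportion"
    gene_probes: dict[str, str] = field(default_factory=dict)
    heatmap: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if not self.simulate:
            for name in ("training_expression", "training_clinical"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"{name} is required unless simulate=True")
                if not Path(path).exists():
                    raise ConfigError(f"{name}: no such file: {path}")
            for name in ("validation_expression", "validation_clinical"):
                path = getattr(self, name)
                if path is not None and not Path(path).exists():
                    raise ConfigError(f"{name}: no such file: {path}")


@dataclass
class PipelineResult:
    selection: object
    model: object
    training_scored: object
    validation_report: object | None
    cox_table: pd.DataFrame
    stratification: object | None
    output_dir: Path


def load_pipeline_config(path) -> PipelineConfig:
    """Load a YAML key:value configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _load_cohort(config: PipelineConfig, expr_path, clin_path) -> CohortDataset:
    expr = read_expression_matrix(expr_path, decimal=config.decimal)
    surv = read_clinical_table(
        clin_path, patient_col=config.patient_col,
        time_col=config.time_col, event_col=config.event_col,
        decimal=config.decimal,
    )
    return align_cohort(expr, surv, single_gene_probes=config.gene_probes or None)


def _km_table(km) -> pd.DataFrame:
    return pd.DataFrame(
        {"time": km.times, "survival": km.survival, "at_risk": km.at_risk}
    )


def _scores_table(scored) -> pd.DataFrame:
    return pd.DataFrame(
        {"patient_id": scored.patient_ids, "score": scored.scores,
         "label": scored.labels}
    )


def _heatmap(cohort, model, scored, path) -> None:
    """Fig-1-style display: probes ordered best-to-worst prognosis
    (ascending HR), samples ordered by increasing risk score."""
    order = np.argsort(scored.scores, kind="stable")
    probes = sorted(model.probes, key=lambda p: p.hazard_ratio)
    rows = [cohort.expression.probe_values(p.probe_id)[order] for p in probes]
    mat = np.asarray(rows)
    mat = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, keepdims=True)
    fig, axes = plt.subplots(
        2, 1, figsize=(8, 6), height_ratios=[3, 1], sharex=False
    )
    im = axes[0].imshow(mat, aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    axes[0].set_yticks(range(len(probes)))
    axes[0].set_yticklabels([p.probe_id for p in probes], fontsize=5)
    axes[0].set_title("Prognostic probes (best to worst) x patients by score")
    fig.colorbar(im, ax=axes[0], label="z-scored expression")
    axes[1].plot(np.sort(scored.scores), lw=1.2)
    axes[1].axhline(model.threshold, color="red", ls="--", lw=0.8,
                    label=f"tau = {model.threshold:.2f}")
    axes[1].set_ylabel("risk score")
    axes[1].set_xlabel("patients (increasing score)")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write the report bundle.

    Stages: probe selection (maxstat + BH), per-probe Cox fits and score
    construction, threshold optimization, transfer to the validation
    cohort, univariate Cox of the risk label, and (when a gene of interest
    is configured or simulated) the three-group score x gene
    stratification.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stale_flag = outdir / "INCOMPLETE"
    stale_flag.write_text("run in progress; outputs may be partial\n")

    gene_probes = dict(config.gene_probes)
    if config.simulate:
        sim = SimulationConfig(seed=config.seed, gene=GeneSpec())
        training_syn, validation_syn = generate_training_validation_pair(sim)
        training, validation = training_syn.dataset, validation_syn.dataset
        gene_probes = dict(training.single_gene_probes or {})
        logger.info("simulated cohorts: %d training / %d validation patients",
                    training.n_patients, validation.n_patients)
    else:
        training = _load_cohort(config, config.training_expression,
                                config.training_clinical)
        validation = None
        if config.validation_expression and config.validation_clinical:
            validation = _load_cohort(config, config.validation_expression,
                                      config.validation_clinical)

    # --- selection ---------------------------------------------------------
    selection = select_prognostic_probesets(
        training, alpha=config.alpha, q_low=config.q_low, q_high=config.q_high
    )
    logger.info("selection: %d probes in, %d selected, %d skipped",
                len(selection.rows), len(selection.selected), len(selection.skipped))

    # --- score model -------------------------------------------------------
    model = fit_risk_score_model(training, selection,
                                 transfer_mode=config.transfer_mode)
    train_scores = compute_scores(training.expression, model.probes)
    training_scored = classify_patients(train_scores, training.patient_ids, model)
    logger.info("score: tau=%.4f, p_high=%.3f, %d/%d training patients high risk",
                model.threshold, model.p_high,
                int((training_scored.labels == "high").sum()), training.n_patients)

    write_selection_table(model.probes, outdir / "selection_table.tsv")
    save_model(model, outdir / "risk_score_model.json")
    _scores_table(training_scored).to_csv(outdir / "scores_training.tsv",
                                          sep="\t", index=False)

    # --- training survival summaries --------------------------------------
    t_time, t_event = training.survival.time, training.survival.event
    for label in ("high", "low"):
        mask = training_scored.labels == label
        if mask.any():
            _km_table(km_estimate(t_time[mask], t_event[mask])).to_csv(
                outdir / f"km_training_{label}.tsv", sep="\t", index=False
            )

    # --- Cox table ---------------------------------------------------------
    cox_rows = []
    risk_indicator = (training_scored.labels == "high").astype(float)
    fit = cox_ph_fit(pd.DataFrame({"risk_score_high": risk_indicator}),
                     t_time, t_event)
    cox_rows.append({"variable": "GE-based risk score",
                     "HR": fit.hazard_ratio[0], "p": fit.p[0]})
    gene_dichotomies = {}
    for gene_name, probe in gene_probes.items():
        if probe not in training.expression.probe_ids:
            logger.warning("gene %s: probe %s absent from training matrix; skipped",
                           gene_name, probe)
            continue
        dich = gene_maxstat_dichotomize(training, probe, gene_name=gene_name,
                                        q_low=config.q_low, q_high=config.q_high)
        gene_dichotomies[gene_name] = dich
        ind = (dich.labels == "high").astype(float)
        gfit = cox_ph_fit(pd.DataFrame({f"{gene_name}_high": ind}), t_time, t_event)
        cox_rows.append({"variable": f"{gene_name} expression",
                         "HR": gfit.hazard_ratio[0], "p": gfit.p[0]})
    cox_table = pd.DataFrame(cox_rows, columns=["variable", "HR", "p"])
    cox_table.to_csv(outdir / "cox_table.tsv", sep="\t", index=False,
                     float_format="%.4f")

    # --- validation --------------------------------------------------------
    validation_report = None
    if validation is not None:
        validation_report = apply_model(model, validation)
        _scores_table(validation_report.scored).to_csv(
            outdir / "scores_validation.tsv", sep="\t", index=False
        )
        for label, km in validation_report.km_by_group.items():
            _km_table(km).to_csv(outdir / f"km_validation_{label}.tsv",
                                 sep="\t", index=False)
        logger.info("validation: %d patients, high-risk fraction %.3f, "
                    "log-rank p=%.3g", len(validation_report.scored.patient_ids),
                    validation_report.scored.high_fraction,
                    validation_report.logrank_p)

    # --- stratification ----------------------------------------------------
    stratification = None
    if gene_dichotomies:
        first = next(iter(gene_dichotomies.values()))
        stratification = three_group_stratify(training_scored, first,
                                              training.survival)
        pd.DataFrame(
            {
                "patient_id": stratification.patient_ids,
                "score_label": training_scored.labels,
                "gene_label": first.labels,
                "group": stratification.groups,
            }
        ).to_csv(outdir / "stratification.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "group": g,
                    "n": stratification.sizes[g],
                    "fraction": stratification.fractions[g],
                    "median_os": format_median(stratification.median_by_group.get(g)),
                }
                for g in stratification.sizes
            ]
        ).to_csv(outdir / "stratification_summary.tsv", sep="\t", index=False)
        logger.info("stratification (%s): sizes %s, log-rank p=%.3g",
                    first.gene, stratification.sizes, stratification.logrank_p)

    if config.heatmap:
        _heatmap(training, model, training_scored, outdir / "heatmap_training.png")

    manifest = {
        "generisk_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "seed": config.seed,
        "n_training": training.n_patients,
        "n_validation": None if validation is None else validation.n_patients,
        "n_selected_probes": len(model.probes),
        "threshold": model.threshold,
        "p_high": model.p_high,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    stale_flag.unlink()
    return PipelineResult(
        selection=selection,
        model=model,
        training_scored=training_scored,
        validation_report=validation_report,
        cox_table=cox_table,
        stratification=stratification,
        output_dir=outdir,
    )
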