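"""Typed containers for expression/survival cohorts and tabular IO.

Expression input is expected to be already normalized on a log-like scale
(e.g. VSN + median-polish probe-set summaries); this module performs no
normalization.  Identifier joins are case-sensitive exact matches, as is
appropriate for GEO-style sample and probe-set identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdentifierError,
    EmptyCohortError,
    FileFormatError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SurvivalData",
    "CohortDataset",
    "read_expression_matrix",
    "read_clinical_table",
    "align_cohort",
    "write_selection_table",
    "read_selection_table",
]


def _check_unique(ids, kind: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise DuplicateIdentifierError(f"duplicated {kind} identifiers: {dupes}")


@dataclass
class ExpressionMatrix:
    """Probes x patients matrix of finite, normalized log-scale intensities."""

    probe_ids: list[str]
    patient_ids: list[str]
    values: np.ndarray
    gene_symbols: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.patient_ids)):
            raise FileFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.patient_ids)} patients"
            )
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.patient_ids, "patient")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FileFormatError(
                f"non-finite expression value at probe {self.probe_ids[i]!r}, "
                f"patient {self.patient_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(probe_id) from None

    def probe_values(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_index(probe_id)]

    def symbol_for(self, probe_id: str) -> str:
        if self.gene_symbols is None:
            return "---"
        return self.gene_symbols.get(probe_id, "---")

    def subset_patients(self, patient_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.patient_ids.index(p) for p in patient_ids]
        return ExpressionMatrix(
            probe_ids=list(self.probe_ids),
            patient_ids=list(patient_ids),
            values=self.values[:, idx],
            gene_symbols=self.gene_symbols,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.patient_ids)


@dataclass
class SurvivalData:
    """Per-patient overall-survival follow-up: time in months, event flag
    (1 = death observed, 0 = right-censored)."""

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.patient_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise FileFormatError("time/event must align 1:1 with patient_ids")
        _check_unique(self.patient_ids, "patient")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise FileFormatError("follow-up times must be finite and > 0")
        if not np.isin(self.event, [0, 1]).all():
            bad = sorted(set(np.asarray(self.event).tolist()) - {0, 1})
            raise FileFormatError(f"event indicator must be 0/1; found {bad}")
        self.event = self.event.astype(int)

    def __len__(self) -> int:
        return len(self.patient_ids)

    def subset(self, patient_ids: list[str]) -> "SurvivalData":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        idx = [pos[p] for p in patient_ids]
        return SurvivalData(list(patient_ids), self.time[idx], self.event[idx])


@dataclass
class CohortDataset:
    """An expression matrix and survival table aligned on the same patients,
    with optional subtype labels and named single-gene probes of interest."""

    expression: ExpressionMatrix
    survival: SurvivalData
    subtype_labels: dict[str, str] | None = None
    single_gene_probes: dict[str, str] | None = None
    dropped_expression_patients: list[str] = field(default_factory=list)
    dropped_survival_patients: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.expression.patient_ids != self.survival.patient_ids:
            raise FileFormatError(
                "expression and survival patients differ; use align_cohort()"
            )

    @property
    def patient_ids(self) -> list[str]:
        return self.expression.patient_ids

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


def read_expression_matrix(path, fmt: str = "tsv_matrix",
                           decimal: str = ".") -> ExpressionMatrix:
    """Read a tab-delimited probes x patients matrix.

    First column holds probe-set identifiers, the header row patient
    identifiers, and the body numeric intensities.  ``decimal=","`` accepts
    decimal-comma cells as printed in some European tables.
    """
    if fmt != "tsv_matrix":
        raise FileFormatError(f"unsupported expression format: {fmt!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, decimal=decimal, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error wording varies
        raise FileFormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FileFormatError(f"{path}: no patient columns found")
    _check_unique(df.index, "probe")
    _check_unique(df.columns, "patient")
    if decimal != ".":
        df = df.apply(lambda col: col.str.replace(decimal, ".", regex=False))
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise FileFormatError(
            f"{path}: non-numeric cell {df.iloc[bad[0], bad[1]]!r} at probe "
            f"{df.index[bad[0]]!r}, patient {df.columns[bad[1]]!r}"
        )
    return ExpressionMatrix(
        probe_ids=df.index.tolist(),
        patient_ids=df.columns.tolist(),
        values=numeric.to_numpy(dtype=float),
    )


def read_clinical_table(path, patient_col: str = "patient_id",
                        time_col: str = "os_months", event_col: str = "os_event",
                        sep: str = "\t", decimal: str = ".") -> SurvivalData:
    """Read a delimited clinical table into :class:`SurvivalData`.

    Rows with non-positive follow-up time are rejected with a logged count;
    an event column outside {0, 1} is a format error.
    """
    try:
        df = pd.read_csv(path, sep=sep, decimal=decimal)
    except Exception as exc:
        raise FileFormatError(f"cannot parse clinical table {path}: {exc}") from exc
    for col in (patient_col, time_col, event_col):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing column {col!r}")
    time = pd.to_numeric(df[time_col], errors="coerce")
    event = pd.to_numeric(df[event_col], errors="coerce")
    if time.isna().any() or event.isna().any():
        raise FileFormatError(f"{path}: non-numeric time or event values")
    if not event.isin([0, 1]).all():
        bad = sorted(set(event) - {0, 1})
        raise FileFormatError(f"{path}: event values outside {{0,1}}: {bad}")
    keep = time > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: rejected %d rows with follow-up time <= 0", path, n_dropped)
    df = df[keep]
    if df.empty:
        raise EmptyCohortError(f"{path}: no valid patients after filtering")
    return SurvivalData(
        patient_ids=df[patient_col].astype(str).tolist(),
        time=time[keep].to_numpy(dtype=float),
        event=event[keep].to_numpy(dtype=int),
    )


def align_cohort(expr: ExpressionMatrix, surv: SurvivalData,
                 subtype_labels: dict[str, str] | None = None,
                 single_gene_probes: dict[str, str] | None = None) -> CohortDataset:
    """Restrict both components to the patient-identifier intersection.

    The canonical patient order is the expression matrix's column order
    restricted to the intersection, which makes the operation idempotent.
    Dropped identifiers are reported on the returned dataset and logged.
    """
    surv_ids = set(surv.patient_ids)
    common = [p for p in expr.patient_ids if p in surv_ids]
    if not common:
        raise EmptyCohortError("expression and survival share no patient identifiers")
    dropped_expr = [p for p in expr.patient_ids if p not in surv_ids]
    expr_ids = set(expr.patient_ids)
    dropped_surv = [p for p in surv.patient_ids if p not in expr_ids]
    if dropped_expr or dropped_surv:
        logger.info(
            "align_cohort: dropped %d expression-only and %d survival-only patients",
            len(dropped_expr), len(dropped_surv),
        )
    if subtype_labels is not None:
        subtype_labels = {p: subtype_labels[p] for p in common if p in subtype_labels}
    return CohortDataset(
        expression=expr.subset_patients(common),
        survival=surv.subset(common),
        subtype_labels=subtype_labels,
        single_gene_probes=single_gene_probes,
        dropped_expression_patients=dropped_expr,
        dropped_survival_patients=dropped_surv,
    )


# Printed precision of the selection table; chosen so the table
# round-trips exactly through text at the precision it declares.
_SELECTION_COLUMNS = [
    "probe_id", "gene_symbol", "cutpoint", "p_raw", "p_adj", "hazard_ratio", "beta",
]


def write_selection_table(table, path) -> None:
    """Write fitted per-probe prognostic parameters, sorted by decreasing HR.

    Columns: probe id, gene symbol, maxstat cutpoint, raw and BH-adjusted p,
    hazard ratio and Cox beta.  HRs are printed to 2 decimals and p-values
    to 4, matching conventional reporting; cutpoint and beta keep full
    precision so the table round-trips losslessly.
    """
    rows = sorted(table, key=lambda r: -r.hazard_ratio)
    df = pd.DataFrame(
        [
            {
                "probe_id": r.probe_id,
                "gene_symbol": r.gene_symbol,
                "cutpoint": np.format_float_positional(r.cutpoint, trim="0"),
                "p_raw": f"{r.p_raw:.4f}" if r.p_raw is not None else "",
                "p_adj": f"{r.p_adj:.4f}" if r.p_adj is not None else "",
                "hazard_ratio": f"{r.hazard_ratio:.2f}",
                "beta": np.format_float_positional(r.beta, trim="0"),
            }
            for r in rows
        ],
        columns=_SELECTION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_selection_table(path, decimal: str = "."):
    """Read a selection table written by :func:`write_selection_table`.

    ``decimal=","`` accepts decimal-comma numerals as printed in some
    published tables.
    """
    from .score import ProbePrognostic  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _SELECTION_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing selection columns {missing}")

    def num(s):
        if s == "":
            return None
        return float(s.replace(decimal, ".") if decimal != "." else s)

    out = []
    for _, row in df.iterrows():
        out.append(
            ProbePrognostic(
                probe_id=row["probe_id"],
                gene_symbol=row["gene_symbol"],
                cutpoint=num(row["cutpoint"]),
                beta=num(row["beta"]),
                hazard_ratio=num(row["hazard_ratio"]),
                p_raw=num(row["p_raw"]),
                p_adj=num(row["p_adj"]),
                check_consistency=False,  # HR printed at 2 dp
            )
        )
    return out
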