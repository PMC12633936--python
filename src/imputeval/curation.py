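"""Dataset curation and median-centring batch correction.

The curation chain is fixed: (1) set biologically impossible (negative)
values missing, (2) drop mostly-missing analytes and empty samples,
(3) fit and apply a control-based median-centring batch correction,
(4) re-check for negatives created by the correction, (5) extract complete
cases. Every removal is logged with a reason.

The correction model is fitted on control animals only (animals in the
control dose group): the grand median (GM) of an analyte is the pooled
median of its 24-hour control samples across all studies, and the study
median (SM) is the per-study median of controls at all timepoints. In
``shift`` mode each cell is corrected as ``x' = x - (SM - GM)``; the
supplementary alternative ``ratio`` mode uses ``x' = x * GM / SM``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "CurationError",
    "CurationLog",
    "CorrectionModel",
    "remove_impossible",
    "drop_sparse",
    "fit_median_centring",
    "apply_correction",
    "complete_cases",
    "curate",
]


class CurationError(ValueError):
    pass


@dataclass
class CurationLog:
    """Audit trail of curation: what was removed or set missing, and why."""

    removed_rows: list[tuple[str, str]] = field(default_factory=list)
    removed_columns: list[tuple[str, str]] = field(default_factory=list)
    cells_set_missing: list[tuple[str, str, str]] = field(default_factory=list)

    REASONS = frozenset(
        {
            "negative",
            "negative-after-correction",
            "mostly-missing",
            "empty",
            "excluded",
            "ratio-undefined",
            "no-controls",
        }
    )

    def _check(self, reason: str) -> str:
        if reason not in self.REASONS:
            raise CurationError(f"unknown curation reason: {reason}")
        return reason

    def add_row(self, sample_id: str, reason: str) -> None:
        self.removed_rows.append((sample_id, self._check(reason)))

    def add_column(self, analyte: str, reason: str) -> None:
        self.removed_columns.append((analyte, self._check(reason)))

    def add_cell(self, sample_id: str, analyte: str, reason: str) -> None:
        self.cells_set_missing.append((sample_id, analyte, self._check(reason)))

    def extend(self, other: "CurationLog") -> "CurationLog":
        self.removed_rows.extend(other.removed_rows)
        self.removed_columns.extend(other.removed_columns)
        self.cells_set_missing.extend(other.cells_set_missing)
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("row", sid, "", r) for sid, r in self.removed_rows]
            + [("column", "", a, r) for a, r in self.removed_columns]
            + [("cell", sid, a, r) for sid, a, r in self.cells_set_missing]
        )
        return pd.DataFrame(rows, columns=["kind", "sample_id", "analyte", "reason"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CorrectionModel:
    """Grand and study control medians with a correction mode."""

    gm: pd.Series  # per analyte
    sm: pd.DataFrame  # study x analyte
    mode: str = "shift"  # "shift" | "ratio"
    #: (study, analyte) pairs with no control observations; left uncorrected.
    no_controls: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("shift", "ratio"):
            raise CurationError(f"unknown correction mode: {self.mode}")
        if not np.isfinite(self.gm.to_numpy(dtype=float)).all():
            raise CurationError("no-controls: grand median undefined for some analyte")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "gm": self.gm.to_dict(),
            "sm": {str(s): row.dropna().to_dict() for s, row in self.sm.iterrows()},
            "no_controls": [[int(s), a] for s, a in self.no_controls],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionModel":
        d = json.loads(Path(path).read_text())
        sm = pd.DataFrame.from_dict(d["sm"], orient="index")
        sm.index = sm.index.astype(int)
        return cls(
            gm=pd.Series(d["gm"]),
            sm=sm,
            mode=d["mode"],
            no_controls=[(int(s), a) for s, a in d["no_controls"]],
        )


def remove_impossible(table: CohortTable) -> tuple[CohortTable, CurationLog]:
    """Set strictly negative analyte values missing (they are biologically
    impossible for serum clinical chemistry) and log each cell."""
    out = table.copy()
    log = CurationLog()
    neg = out.X < 0
    for sid, analyte in zip(*np.nonzero(neg.to_numpy())):
        log.add_cell(out.X.index[sid], out.X.columns[analyte], "negative")
    out.X = out.X.mask(neg)
    return out, log


def drop_sparse(
    table: CohortTable,
    max_col_missing: float = 0.40,
    drop_empty_rows: bool = True,
) -> tuple[CohortTable, CurationLog]:
    """Drop mostly-missing analytes and (optionally) all-missing samples.

    A column is retained when its missing fraction is <= ``max_col_missing``
    (the boundary is kept: 40% missing at the default threshold survives).
    """
    if not 0.0 <= max_col_missing <= 1.0:
        raise CurationError("max_col_missing must lie in [0, 1]")
    log = CurationLog()
    X = table.X
    col_frac = X.isna().mean()
    keep_cols = col_frac.index[col_frac <= max_col_missing]
    for a in col_frac.index.difference(keep_cols):
        log.add_column(a, "mostly-missing")
    if len(keep_cols) == 0:
        raise CurationError("empty-after-filter: all analyte columns removed")
    X = X[list(keep_cols)]
    meta = table.meta
    if drop_empty_rows:
        empty = X.isna().all(axis=1)
        for sid in X.index[empty]:
            log.add_row(sid, "empty")
        X = X[~empty]
        meta = meta.loc[X.index]
    return CohortTable(X.copy(), meta.copy()), log


def exclude_rows(table: CohortTable, sample_ids: list[str]) -> tuple[CohortTable, CurationLog]:
    """Remove an explicit exclusion list (failed experiments etc.)."""
    log = CurationLog()
    present = [s for s in sample_ids if s in table.X.index]
    for sid in present:
        log.add_row(sid, "excluded")
    keep = ~table.X.index.isin(present)
    return CohortTable(table.X[keep].copy(), table.meta[keep].copy()), log


def fit_median_centring(
    table: CohortTable,
    mode: str = "shift",
    gm_all_timepoints: bool = False,
) -> CorrectionModel:
    """Fit GM/SM from control animals.

    GM uses the 24-hour control samples pooled across studies (set
    ``gm_all_timepoints`` to pool every control timepoint instead); SM uses
    each study's controls at all timepoints. Missing cells are excluded from
    every median. Studies with no control observation for an analyte are
    recorded and skipped at application time.
    """
    ctrl = table.is_control
    if not ctrl.any():
        raise CurationError("no-controls: table has no control rows")
    gm_rows = ctrl if gm_all_timepoints else (ctrl & (table.meta["timepoint_h"] == 24))
    gm = table.X[gm_rows].median()
    sm = table.X[ctrl].groupby(table.meta.loc[ctrl, "study_id"]).median()
    # make sure every study present in the table appears in SM
    sm = sm.reindex(sorted(table.meta["study_id"].unique()))
    no_controls = [
        (int(s), a) for s in sm.index for a in sm.columns if pd.isna(sm.loc[s, a])
    ]
    return CorrectionModel(gm=gm, sm=sm, mode=mode, no_controls=no_controls)


def apply_correction(
    table: CohortTable, model: CorrectionModel
) -> tuple[CohortTable, CurationLog]:
    """Apply the fitted correction to all rows (controls and non-controls).

    Shift mode subtracts ``SM - GM`` per (study, analyte); ratio mode
    multiplies by ``GM / SM``. Cells made negative by the shift are set
    missing and logged; ratio cells with ``SM == 0`` are left uncorrected
    and logged.
    """
    missing_cols = [a for a in table.X.columns if a not in model.gm.index]
    if missing_cols:
        raise CurationError(f"model not fitted for analytes: {missing_cols}")
    out = table.copy()
    log = CurationLog()
    analytes = list(table.X.columns)
    sm = model.sm.reindex(columns=analytes)
    gm = model.gm[analytes]
    study = out.meta["study_id"]
    sm_rows = sm.loc[study].to_numpy()  # per-row SM
    gm_row = gm.to_numpy()
    X = out.X.to_numpy(dtype=float)
    uncorrectable = ~np.isfinite(sm_rows)  # no-controls cells stay untouched
    if model.mode == "shift":
        corrected = X - (sm_rows - gm_row)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = gm_row / sm_rows
        bad = sm_rows == 0
        if bad.any():
            for i, j in zip(*np.nonzero(bad & ~np.isnan(X))):
                log.add_cell(out.X.index[i], analytes[j], "ratio-undefined")
        uncorrectable |= bad
        with np.errstate(invalid="ignore"):
            corrected = X * factor
    corrected = np.where(uncorrectable, X, corrected)
    if model.mode == "shift":
        neg = corrected < 0  # NaN-safe: NaN compares False
        for i, j in zip(*np.nonzero(neg)):
            log.add_cell(out.X.index[i], analytes[j], "negative-after-correction")
        corrected[neg] = np.nan
    out.X = pd.DataFrame(corrected, index=out.X.index, columns=analytes)
    return out, log


def complete_cases(table: CohortTable) -> CohortTable:
    """Rows with no missing analyte values; metadata preserved."""
    keep = table.X.notna().all(axis=1)
    if not keep.any():
        raise CurationError("no-complete-cases")
    return CohortTable(table.X[keep].copy(), table.meta[keep].copy())


def curate(
    table: CohortTable,
    mode: str = "shift",
    max_col_missing: float = 0.40,
    exclude: list[str] | None = None,
    gm_all_timepoints: bool = False,
) -> tuple[CohortTable, CorrectionModel, CurationLog]:
    """Run the canonical curation chain and return the complete-case table.

    Order is fixed: exclusions -> impossible values -> sparsity filters ->
    fit/apply median centring -> re-check negatives (inside apply) ->
    complete cases.
    """
    log = CurationLog()
    if exclude:
        table, l0 = exclude_rows(table, exclude)
        log.extend(l0)
    table, l1 = remove_impossible(table)
    table, l2 = drop_sparse(table, max_col_missing=max_col_missing)
    model = fit_median_centring(table, mode=mode, gm_all_timepoints=gm_all_timepoints)
    table, l3 = apply_correction(table, model)
    cc = complete_cases(table)
    log.extend(l1).extend(l2).extend(l3)
    return cc, model, log
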