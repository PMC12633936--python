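"""The strategy grid: feature-set assembly crossed with centre handling.

A strategy is an engine (iterative ``missforest`` or chained ``micerf``)
crossed with a feature set and a handling mode for the centre variable C
(the company label):

======================  ====================================================
feature set             predictor columns besides the analytes themselves
======================  ====================================================
``X``                   none
``X_C``                 C (when C is used as a variable)
``X_Y_C``               the metadata block Y without the toxin label, plus C
``X_Y_TOXIN_C``         Y including the toxin label, plus C
======================  ====================================================

``c_mode='variable'`` includes C as a categorical predictor;
``c_mode='strata'`` instead runs the engine independently within each level
of C and re-joins rows (C itself is then constant within a stratum and is
excluded from the features). The canonical grid has exactly 11 cells: the
toxin-bearing feature set exists only for the chained engine, because the
iterative engine caps factors at 53 levels and the toxin factor has 107.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seeds import derive_seed
from .engines import (
    EngineError,
    EngineParams,
    ImputationInput,
    merge_imputations,
    micerf_impute,
    missforest_impute,
)

__all__ = [
    "StrategySpec",
    "StratumInfeasibleError",
    "canonical_grid",
    "assemble_features",
    "run_strategy",
    "FEATURE_SETS",
    "ENGINES",
]

ENGINES = ("missforest", "micerf")
FEATURE_SETS = ("X", "X_C", "X_Y_C", "X_Y_TOXIN_C")
C_MODES = ("variable", "strata")

_ENGINE_LABEL = {"missforest": "missForest", "micerf": "MICErf"}
_FS_LABEL = {"X": "X", "X_C": "X + C", "X_Y_C": "X + Y_All + C", "X_Y_TOXIN_C": "X + Y_All+Toxin + C"}

#: Y-block columns used as features (the toxin label is handled separately).
Y_FEATURES = ("timepoint_h", "dose_group", "target_organ", "euthanasia_group")


class StratumInfeasibleError(EngineError):
    """A stratum where some analyte cannot be imputed (< 2 observed values)."""

    def __init__(self, failures: list[tuple[str, str, int]]):
        self.failures = failures  # (stratum, column, n_observed)
        detail = "; ".join(f"{s}/{c}: {n} observed" for s, c, n in failures)
        super().__init__(f"stratum-infeasible: {detail}")


@dataclass(frozen=True)
class StrategySpec:
    """One cell of the strategy grid."""

    engine: str
    feature_set: str
    c_mode: str

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine: {self.engine}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set: {self.feature_set}")
        if self.c_mode not in C_MODES:
            raise ValueError(f"unknown c_mode: {self.c_mode}")
        if self.engine == "missforest" and self.feature_set == "X_Y_TOXIN_C":
            raise ValueError(
                "factor-cap-exceeded: the iterative engine caps factors at 53 "
                "levels; the toxin factor cannot be included"
            )
        if self.feature_set == "X" and self.c_mode == "variable":
            pass  # plain pooled imputation without C

    @property
    def label(self) -> str:
        """Canonical display label, e.g. 'missForest X + Y_All + C_Strata'."""
        eng = _ENGINE_LABEL[self.engine]
        fs = _FS_LABEL[self.feature_set]
        if self.feature_set == "X":
            if self.c_mode == "strata":
                return f"{eng} X + C_Strata"
            return f"{eng} X"
        suffix = "Strata" if self.c_mode == "strata" else "Variable"
        return f"{eng} {fs}_{suffix}"


def canonical_grid() -> list[StrategySpec]:
    """The canonical 11-cell grid.

    Six chained-engine cells (including the toxin-bearing one) and five
    iterative-engine cells. ``X`` with ``c_mode='strata'`` is the
    'X + C_Strata' row: no extra features, stratified by C.
    """
    grid: list[StrategySpec] = []
    for engine in ("micerf", "missforest"):
        grid.append(StrategySpec(engine, "X", "variable"))
        grid.append(StrategySpec(engine, "X", "strata"))
        grid.append(StrategySpec(engine, "X_C", "variable"))
        grid.append(StrategySpec(engine, "X_Y_C", "strata"))
        grid.append(StrategySpec(engine, "X_Y_C", "variable"))
        if engine == "micerf":
            grid.append(StrategySpec(engine, "X_Y_TOXIN_C", "variable"))
    return grid


def _check_alignment(X: pd.DataFrame, Y: pd.DataFrame | None, C: pd.Series | None) -> None:
    if Y is not None and not X.index.equals(Y.index):
        raise ValueError("alignment-error: X and Y row indices differ")
    if C is not None and not X.index.equals(C.index):
        raise ValueError("alignment-error: X and C row indices differ")


def assemble_features(
    X_missing: pd.DataFrame,
    Y: pd.DataFrame | None,
    C: pd.Series | None,
    spec: StrategySpec,
) -> ImputationInput:
    """Build the engine input for a strategy cell.

    Target columns are always exactly the analytes of X; the feature set
    decides which metadata columns ride along as predictors. In strata mode
    C is excluded (it is constant within each stratum).
    """
    _check_alignment(X_missing, Y, C)
    parts = [X_missing]
    if spec.feature_set in ("X_Y_C", "X_Y_TOXIN_C"):
        if Y is None:
            raise ValueError("alignment-error: feature set needs the Y block")
        cols = [c for c in Y_FEATURES if c in Y.columns]
        Yf = Y[cols].astype(str)
        parts.append(Yf)
        if spec.feature_set == "X_Y_TOXIN_C":
            parts.append(Y[["toxin"]].astype(str))
    if spec.feature_set != "X" and spec.c_mode == "variable":
        if C is None:
            raise ValueError("alignment-error: feature set needs C")
        parts.append(C.astype(str).rename("company"))
    data = pd.concat(parts, axis=1)
    return ImputationInput(data=data, target_columns=list(X_missing.columns))


def _run_engine(input: ImputationInput, spec: StrategySpec, params: EngineParams) -> pd.DataFrame:
    if spec.engine == "missforest":
        completed, _ = missforest_impute(input, params)
        return completed
    chains = micerf_impute(input, params)
    return merge_imputations(chains)


def run_strategy(
    X_missing: pd.DataFrame,
    Y: pd.DataFrame | None,
    C: pd.Series | None,
    spec: StrategySpec,
    params: EngineParams,
) -> pd.DataFrame:
    """Run one strategy cell and return the completed analyte block.

    In strata mode rows are partitioned by the level of C, the engine runs
    independently per stratum with a sub-seed derived from the stratum
    label, and the pieces are re-joined in the original row order. A single
    C level degenerates to the pooled run (same seed, C excluded). Strata
    where any analyte has fewer than two observed values raise
    :class:`StratumInfeasibleError` listing every infeasible (stratum,
    analyte) pair.
    """
    if spec.c_mode == "variable":
        input = assemble_features(X_missing, Y, C, spec)
        return _run_engine(input, spec, params)[list(X_missing.columns)]

    if C is None:
        raise ValueError("alignment-error: strata mode needs C")
    _check_alignment(X_missing, Y, C)
    levels = sorted(C.unique())
    if len(levels) == 1:
        input = assemble_features(X_missing, Y, None, spec)
        return _run_engine(input, spec, params)[list(X_missing.columns)]

    failures: list[tuple[str, str, int]] = []
    for level in levels:
        rows = C == level
        sub = X_missing[rows]
        for col in sub.columns:
            n_obs = int(sub[col].notna().sum())
            if n_obs < 2:
                failures.append((str(level), col, n_obs))
    if failures:
        raise StratumInfeasibleError(failures)

    pieces = []
    for level in levels:
        rows = C == level
        sub_input = assemble_features(
            X_missing[rows], Y[rows] if Y is not None else None, None, spec
        )
        sub_params = params.with_seed(derive_seed(params.seed, "stratum", str(level)))
        pieces.append(_run_engine(sub_input, spec, sub_params)[list(X_missing.columns)])
    joined = pd.concat(pieces).loc[X_missing.index]
    return joined
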