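"""Random-forest imputation engines.

Two engines are implemented from first principles:

``missforest_impute``
    Iterative random-forest imputation. Missing cells are initialised with
    column means (modes for categoricals); columns are then revisited in
    order of increasing missingness, each re-imputed by a forest fitted on
    the rows where it is observed. Sweeps continue until the normalised
    change between consecutive completions rises, at which point the
    previous sweep's completion is returned.

``micerf_impute``
    Multiple imputation by chained equations with random-forest
    conditionals. Each of ``mice_m`` chains starts from random draws of
    observed values and performs ``mice_iterations`` sweeps; a missing cell
    is filled by picking one tree of the column's forest uniformly at random
    and drawing a donor uniformly from the observed responses in the leaf
    the cell falls into. Imputed values are therefore always observed donor
    values from the same column. Chains are merged into one completed table
    by ``merge_imputations`` (cell-wise mean, modal value for categoricals).

Observed cells are never modified by either engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .forest import RandomForest

__all__ = [
    "EngineError",
    "EngineParams",
    "ImputationInput",
    "ConvergenceInfo",
    "initial_impute",
    "missforest_impute",
    "micerf_impute",
    "merge_imputations",
]


class EngineError(ValueError):
    pass


def _default_mtry(p: int) -> int:
    return max(1, int(np.floor(np.sqrt(p))))


@dataclass(frozen=True)
class EngineParams:
    """Hyperparameters shared by both engines.

    ``ntree`` defaults to 10 (the evaluation's setting for both engines);
    ``mice_iterations`` to the recommended 5; ``max_factor_levels`` to 53,
    the per-factor cap of the iterative engine. ``mtry_rule`` maps the
    feature count to the per-split candidate count (default floor(sqrt(p))).
    """

    ntree: int = 10
    mice_iterations: int = 5
    mice_m: int = 5
    max_iter: int = 10
    min_leaf: int = 5
    max_factor_levels: int = 53
    mtry_rule: object = field(default=_default_mtry, repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ntree", "mice_iterations", "mice_m", "max_iter", "min_leaf"):
            if getattr(self, name) < 1:
                raise EngineError(f"{name} must be >= 1")
        if self.max_factor_levels < 2:
            raise EngineError("max_factor_levels must be >= 2")

    def with_seed(self, seed: int) -> "EngineParams":
        return replace(self, seed=seed)


@dataclass
class ImputationInput:
    """A mixed-type table plus the designation of which columns to impute.

    ``data`` holds the imputation targets (continuous analytes, possibly
    with missing cells) together with fully observed feature columns
    (categorical metadata, centre labels, ...). ``target_columns`` are the
    columns the engines fill in; all other columns act as predictors only.
    """

    data: pd.DataFrame
    target_columns: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in self.target_columns if c not in self.data.columns]
        if missing:
            raise EngineError(f"target columns not in data: {missing}")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.target_columns]

    @property
    def observed_mask(self) -> pd.DataFrame:
        return self.data[self.target_columns].notna()


@dataclass
class ConvergenceInfo:
    """Trace of the iterative engine's stopping criterion."""

    iterations_run: int
    delta_trace: list[float]
    stopped_reason: str  # "criterion-rise" | "max-iter" | "no-missing"

    def __post_init__(self) -> None:
        if len(self.delta_trace) != self.iterations_run:
            raise EngineError("delta_trace length must equal iterations_run")


def _is_categorical(s: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(s)


def _check_factor_cap(input: ImputationInput, params: EngineParams) -> None:
    for c in input.data.columns:
        s = input.data[c]
        if _is_categorical(s):
            levels = s.dropna().nunique()
            if levels > params.max_factor_levels:
                raise EngineError(
                    f"factor-cap-exceeded: column '{c}' has {levels} levels "
                    f"(cap {params.max_factor_levels})"
                )


def initial_impute(input: ImputationInput) -> pd.DataFrame:
    """Column-mean (continuous) / column-mode (categorical) initialisation."""
    out = input.data.copy()
    for c in out.columns:
        col = out[c]
        if not col.isna().any():
            continue
        obs = col.dropna()
        if obs.empty:
            raise EngineError(f"column-all-missing: '{c}'")
        fill = obs.mode().iloc[0] if _is_categorical(col) else obs.mean()
        out[c] = col.fillna(fill)
    return out


class _FeatureCodec:
    """One-hot encodes the categorical columns of a working table once.

    Target (numeric) columns are written into a shared float32 feature
    buffer and refreshed as their imputations change; categorical features
    are fully observed and encoded a single time.
    """

    def __init__(self, data: pd.DataFrame, target_columns: list[str]) -> None:
        self.targets = list(target_columns)
        self.numeric_features = [
            c for c in data.columns if c not in target_columns and not _is_categorical(data[c])
        ]
        cat_cols = [c for c in data.columns if c not in target_columns and _is_categorical(data[c])]
        if cat_cols:
            if data[cat_cols].isna().any().any():
                raise EngineError("categorical feature columns must be fully observed")
            onehot = pd.get_dummies(data[cat_cols].astype(str), dtype=np.float32)
            self._static = np.ascontiguousarray(onehot.to_numpy(dtype=np.float32))
        else:
            self._static = np.empty((len(data), 0), dtype=np.float32)
        if self.numeric_features:
            self._static = np.hstack(
                [data[self.numeric_features].to_numpy(dtype=np.float32), self._static]
            )
        self.n_target = len(self.targets)
        self.buffer = np.empty((len(data), self.n_target + self._static.shape[1]), dtype=np.float32)
        self.buffer[:, self.n_target :] = self._static

    def refresh(self, work: np.ndarray) -> None:
        """Copy current target values (float64 working matrix) into the buffer."""
        self.buffer[:, : self.n_target] = work

    def features_for(self, j: int) -> np.ndarray:
        """Feature matrix excluding target column j (view-free copy)."""
        return np.ascontiguousarray(np.delete(self.buffer, j, axis=1))

    @property
    def p_features(self) -> int:
        return self.buffer.shape[1] - 1


def _visit_order(miss_counts: np.ndarray) -> np.ndarray:
    """Columns in order of increasing missingness, ties by position."""
    return np.argsort(miss_counts, kind="stable")


def _prepare(input: ImputationInput) -> tuple[np.ndarray, np.ndarray, list[str]]:
    targets = input.target_columns
    work = input.data[targets].to_numpy(dtype=np.float64)
    if not all(pd.api.types.is_numeric_dtype(input.data[c]) for c in targets):
        raise EngineError("target columns must be continuous analytes")
    miss = np.isnan(work)
    for j, c in enumerate(targets):
        if (~miss[:, j]).sum() == 0:
            raise EngineError(f"column-all-missing: '{c}'")
    return work, miss, targets


def missforest_impute(
    input: ImputationInput, params: EngineParams
) -> tuple[pd.DataFrame, ConvergenceInfo]:
    """Iterative random-forest imputation of the target columns.

    Deterministic given ``params.seed``. Returns the completed table (all
    input columns, observed cells bit-identical) and the convergence trace.
    """
    _check_factor_cap(input, params)
    work, miss, targets = _prepare(input)
    for j, c in enumerate(targets):
        if miss[:, j].any() and (~miss[:, j]).sum() < 2:
            raise EngineError(f"column-underdetermined: '{c}' has < 2 observed values")

    if not miss.any():
        return input.data.copy(), ConvergenceInfo(1, [0.0], "no-missing")

    rng = np.random.default_rng(derive_seed("missforest", params.seed))
    codec = _FeatureCodec(input.data, targets)
    order = _visit_order(miss.sum(axis=0))
    mtry = params.mtry_rule(codec.p_features)

    # column-mean initialisation
    for j in range(len(targets)):
        if miss[:, j].any():
            work[miss[:, j], j] = work[~miss[:, j], j].mean()

    prev = work.copy()
    best = work.copy()
    deltas: list[float] = []
    reason = "max-iter"
    iterations = 0
    for sweep in range(params.max_iter):
        iterations += 1
        codec.refresh(work)
        for j in order:
            mis = miss[:, j]
            if not mis.any():
                continue
            obs = ~mis
            F = codec.features_for(j)
            forest = RandomForest(params.ntree, mtry, params.min_leaf, rng).fit(
                F[obs], work[obs, j]
            )
            work[mis, j] = forest.predict(F[mis])
            codec.buffer[mis, j] = work[mis, j]
        num = float(((work - prev) ** 2)[miss].sum())
        den = float((work**2)[miss].sum())
        delta = num / den if den > 0 else 0.0
        deltas.append(delta)
        if sweep > 0 and delta >= deltas[-2]:
            reason = "criterion-rise"
            break
        best = work.copy()  # last sweep with a decreasing criterion
        prev = work.copy()

    out = input.data.copy()
    imputed = out[targets].to_numpy(dtype=np.float64)
    imputed[miss] = best[miss]
    out[targets] = imputed
    return out, ConvergenceInfo(iterations, deltas, reason)


def micerf_impute(input: ImputationInput, params: EngineParams) -> list[pd.DataFrame]:
    """Chained-equations imputation with random-forest conditionals.

    Returns ``params.mice_m`` completed tables (one per chain). Every
    imputed value is an observed donor value from its own column. Unlike the
    iterative engine, no factor-level cap applies: categorical features of
    any cardinality are one-hot encoded.
    """
    work0, miss, targets = _prepare(input)
    for j, c in enumerate(targets):
        if miss[:, j].any() and (~miss[:, j]).sum() < 2:
            raise EngineError(f"column-underdetermined: '{c}' has < 2 observed values")

    if not miss.any():
        return [input.data.copy() for _ in range(params.mice_m)]

    codec = _FeatureCodec(input.data, targets)
    order = _visit_order(miss.sum(axis=0))
    mtry = params.mtry_rule(codec.p_features)

    chains: list[pd.DataFrame] = []
    for m in range(params.mice_m):
        rng = np.random.default_rng(derive_seed("micerf", params.seed, m))
        work = work0.copy()
        # initialise missing cells by random draws from the observed values
        for j in range(len(targets)):
            mis = miss[:, j]
            if mis.any():
                donors = work0[~mis, j]
                work[mis, j] = rng.choice(donors, size=int(mis.sum()), replace=True)
        for _ in range(params.mice_iterations):
            codec.refresh(work)
            for j in order:
                mis = miss[:, j]
                if not mis.any():
                    continue
                obs = ~mis
                F = codec.features_for(j)
                F_obs, F_mis = F[obs], F[mis]
                y_obs = work[obs, j]
                forest = RandomForest(params.ntree, mtry, params.min_leaf, rng).fit(F_obs, y_obs)
                leaf_obs = forest.apply(F_obs)
                leaf_mis = forest.apply(F_mis)
                tree_pick = rng.integers(0, params.ntree, size=int(mis.sum()))
                vals = np.empty(int(mis.sum()))
                for i in range(vals.size):
                    t = tree_pick[i]
                    donors = y_obs[leaf_obs[:, t] == leaf_mis[i, t]]
                    if donors.size == 0:  # empty leaf: climb to an ancestor
                        members = forest.node_donors(t, F_mis[i], F_obs)
                        donors = y_obs[members]
                    vals[i] = donors[rng.integers(0, donors.size)]
                work[mis, j] = vals
                codec.buffer[mis, j] = work[mis, j]
        out = input.data.copy()
        imputed = out[targets].to_numpy(dtype=np.float64)
        imputed[miss] = work[miss]
        out[targets] = imputed
        chains.append(out)
    return chains


def merge_imputations(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Collapse multiple completed tables into one.

    Continuous cells are averaged; categorical cells take the modal value
    (ties broken by lexicographic level order). Observed cells are identical
    across tables by construction and pass through unchanged.
    """
    if not tables:
        raise EngineError("merge-mismatch: no tables to merge")
    first = tables[0]
    for t in tables[1:]:
        if t.shape != first.shape or list(t.columns) != list(first.columns):
            raise EngineError("merge-mismatch: tables differ in shape or columns")
        if any(_is_categorical(t[c]) != _is_categorical(first[c]) for c in first.columns):
            raise EngineError("merge-mismatch: tables differ in column types")
    if len(tables) == 1:
        return first.copy()
    out = first.copy()
    for c in first.columns:
        if _is_categorical(first[c]):
            stacked = pd.concat([t[c] for t in tables], axis=1)
            out[c] = stacked.apply(
                lambda row: sorted(row.mode())[0], axis=1
            )
        else:
            out[c] = np.mean([t[c].to_numpy(dtype=float) for t in tables], axis=0)
    return out
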