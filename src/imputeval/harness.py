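"""Experiment harness: the full mechanisms x proportions x strategies grid.

For every (sample size, mechanism, proportion) cell the harness subsamples
complete rows, draws one mask per repetition, runs every strategy on the
identical masked input (a paired design: strategies within a repetition see
the same mask, verified by a recorded mask hash), scores the completed
tables against the truth, and aggregates repetitions into mean +- SD and a
per-condition ranking of strategies by mean full MAE.

Strategy failures (e.g. an infeasible stratum in stratified chained-engine
runs at small N) are recorded as flagged rows rather than aborting the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .amputation import DEFAULT_PROPORTIONS, apply_mask, make_mask
from .cohort import RelationshipPair
from .engines import EngineError, EngineParams
from .metrics import distribution_shift, mae, nrmse, relationship_bias
from .strategies import StrategySpec, StratumInfeasibleError, run_strategy, canonical_grid

__all__ = ["ExperimentConfig", "run_grid", "aggregate", "rank_strategies"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid definition and seeds for one benchmark run."""

    mechanisms: tuple[str, ...] = ("MCAR", "MAR", "MNAR")
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    sample_sizes: tuple[int, ...] = (3817, 500, 50)
    repetitions: int = 20
    strategies: tuple[StrategySpec, ...] = tuple(canonical_grid())
    engine_params: EngineParams = EngineParams()
    master_seed: int = 0
    mae_pooling: str = "sd"
    #: reuse one mask per (N, mechanism, proportion) across repetitions
    fixed_masks: bool = False
    #: pairs scored by the relationship-bias metric
    pairs: tuple[RelationshipPair, ...] = ()
    #: per-cell result files written here when set (makes runs resumable)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        for m in self.proportions:
            if not 0.0 < m < 1.0:
                raise ValueError("proportions must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "strategies" in d:
            d["strategies"] = tuple(StrategySpec(**s) for s in d["strategies"])
        if "engine_params" in d:
            d["engine_params"] = EngineParams(**d["engine_params"])
        if "pairs" in d:
            d["pairs"] = tuple(RelationshipPair(**p) for p in d["pairs"])
        for key in ("mechanisms", "proportions", "sample_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _subsample(X: pd.DataFrame, n: int, seed: int) -> pd.Index:
    if n > len(X):
        raise ValueError(f"insufficient-rows: requested {n}, cohort has {len(X)}")
    if n == len(X):
        return X.index
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(len(X), size=n, replace=False))
    return X.index[pos]


def _score(
    X_true: pd.DataFrame,
    completed: pd.DataFrame,
    mask_pattern: pd.DataFrame,
    pairs: tuple[RelationshipPair, ...],
    pooling: str,
) -> dict[str, float]:
    rec: dict[str, float] = {
        "nrmse": nrmse(X_true, completed, mask_pattern),
        "mae_full": mae(X_true, completed, mask_pattern, scope="full", pooling=pooling),
    }
    partial = mae(X_true, completed, mask_pattern, scope="partial")
    for a, v in partial.items():
        rec[f"mae_partial_{a}"] = v
    ks = [
        distribution_shift(X_true[c], completed[c])
        for c in X_true.columns
        if mask_pattern[c].any()
    ]
    rec["dist_shift_mean"] = float(np.mean(ks))
    rec["dist_shift_max"] = float(np.max(ks))
    for pair in pairs:
        bias = relationship_bias(X_true, completed, mask_pattern, pair)
        for k, v in bias.items():
            rec[f"bias_{pair.label}_{k}"] = v
    return rec


def run_grid(
    X_complete: pd.DataFrame,
    Y: pd.DataFrame | None,
    C: pd.Series | None,
    config: ExperimentConfig,
) -> pd.DataFrame:
    """Run the full grid and return one record per strategy x repetition.

    Records carry the condition coordinates, the mask content hash (equal
    across strategies within a repetition -- the paired design), the metric
    values, and failure flags. Deterministic given ``config.master_seed``.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    records: list[dict] = []
    for n in config.sample_sizes:
        rows = _subsample(X_complete, n, derive_seed(config.master_seed, "subsample", n))
        Xn = X_complete.loc[rows]
        Yn = Y.loc[rows] if Y is not None else None
        Cn = C.loc[rows] if C is not None else None
        for mech in config.mechanisms:
            for prop in config.proportions:
                cell_name = f"N{n}_{mech}_M{int(round(prop * 100))}"
                if out_dir and (out_dir / f"{cell_name}.csv").exists():
                    cached = pd.read_csv(out_dir / f"{cell_name}.csv")
                    records.extend(cached.to_dict("records"))
                    continue
                cell_records = _run_cell(Xn, Yn, Cn, n, mech, prop, config)
                if out_dir:
                    pd.DataFrame(cell_records).to_csv(out_dir / f"{cell_name}.csv", index=False)
                records.extend(cell_records)
    return pd.DataFrame(records)


def _run_cell(
    Xn: pd.DataFrame,
    Yn: pd.DataFrame | None,
    Cn: pd.Series | None,
    n: int,
    mech: str,
    prop: float,
    config: ExperimentConfig,
) -> list[dict]:
    records = []
    for rep in range(config.repetitions):
        mask_key = (config.master_seed, n, mech, prop) if config.fixed_masks else (
            config.master_seed,
            n,
            mech,
            prop,
            rep,
        )
        mask = make_mask(Xn, mech, prop, seed=derive_seed(*mask_key))
        X_missing = apply_mask(Xn, mask)
        mask_hash = mask.content_hash()
        for spec in config.strategies:
            base = {
                "sample_size": n,
                "mechanism": mech,
                "proportion": prop,
                "strategy": spec.label,
                "engine": spec.engine,
                "c_mode": spec.c_mode,
                "feature_set": spec.feature_set,
                "repetition": rep,
                "mask_hash": mask_hash,
                "failed": False,
                "failure_reason": "",
            }
            eng_seed = derive_seed(config.master_seed, n, mech, prop, rep, spec.label)
            params = config.engine_params.with_seed(eng_seed)
            try:
                completed = run_strategy(X_missing, Yn, Cn, spec, params)
                base.update(_score(Xn, completed, mask.pattern, config.pairs, config.mae_pooling))
            except (StratumInfeasibleError, EngineError) as exc:
                base["failed"] = True
                base["failure_reason"] = str(exc)
            records.append(base)
    return records


_METRIC_PREFIXES = ("nrmse", "mae_", "dist_shift", "bias_")


def _metric_columns(records: pd.DataFrame) -> list[str]:
    return [c for c in records.columns if c.startswith(_METRIC_PREFIXES)]


_CELL_KEYS = ["sample_size", "mechanism", "proportion", "strategy"]


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of every metric over repetitions.

    A single repetition yields an undefined (NaN) SD, not 0. Each
    (condition, strategy) row also carries the fraction of repetitions that
    failed; metric summaries are computed over the non-failed repetitions.
    """
    metric_cols = _metric_columns(records)
    grouped = records.groupby(_CELL_KEYS, sort=True)
    rows = []
    for keys, grp in grouped:
        ok = grp[~grp["failed"]]
        row = dict(zip(_CELL_KEYS, keys))
        row["n_repetitions"] = len(grp)
        row["failure_fraction"] = float(grp["failed"].mean())
        for c in metric_cols:
            vals = ok[c].dropna()
            row[f"{c}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{c}_sd"] = float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def rank_strategies(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Rank strategies 1 (best) .. k (worst) per condition by mean full MAE.

    Ties are broken by mean NRMSE, then by label order. Strategies with any
    failed repetition are flagged and ranked after all unflagged ones (among
    themselves by label).
    """
    keys = ["sample_size", "mechanism", "proportion"]
    out = []
    for cell, grp in aggregated.groupby(keys, sort=True):
        ok = grp[grp["failure_fraction"] == 0.0].sort_values(
            ["mae_full_mean", "nrmse_mean", "strategy"]
        )
        bad = grp[grp["failure_fraction"] > 0.0].sort_values("strategy")
        ordered = pd.concat([ok, bad])
        for rank, (_, row) in enumerate(ordered.iterrows(), start=1):
            out.append(
                dict(
                    zip(keys, cell),
                    strategy=row["strategy"],
                    rank=rank,
                    mae_full_mean=row["mae_full_mean"],
                    failed=row["failure_fraction"] > 0.0,
                )
            )
    return pd.DataFrame(out)
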