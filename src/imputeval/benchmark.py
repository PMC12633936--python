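"""Model/Results front-end for the imputation benchmark.

``ImputationBenchmark`` is built from a complete analyte block (plus
metadata) and an :class:`~imputeval.harness.ExperimentConfig`; ``fit()``
executes the grid and returns a :class:`BenchmarkResults` carrying the raw
records, aggregated means and SDs, the per-condition strategy ranking, and a
text ``summary()``.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .curation import curate
from .harness import ExperimentConfig, aggregate, rank_strategies, run_grid

__all__ = ["ImputationBenchmark", "BenchmarkResults"]


class ImputationBenchmark:
    """Strategy-evaluation experiment over a complete cohort.

    Parameters
    ----------
    X : complete samples-by-analytes block (the ground truth).
    Y : metadata feature block aligned to X (may be None).
    C : centre/outcome variable aligned to X (may be None).
    config : grid definition; defaults to the full canonical grid.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        Y: pd.DataFrame | None = None,
        C: pd.Series | None = None,
        config: ExperimentConfig | None = None,
    ) -> None:
        if X.isna().any().any():
            raise ValueError("X must be complete; run curation/complete-case extraction first")
        self.X = X
        self.Y = Y
        self.C = C
        self.config = config or ExperimentConfig()

    @classmethod
    def from_cohort(
        cls, cohort: CohortTable, config: ExperimentConfig | None = None
    ) -> "ImputationBenchmark":
        """Build from an already-complete cohort table."""
        return cls(cohort.X, cohort.Y, cohort.C, config)

    @classmethod
    def from_raw_cohort(
        cls,
        cohort: CohortTable,
        config: ExperimentConfig | None = None,
        correction_mode: str = "shift",
        max_col_missing: float = 0.40,
    ) -> "ImputationBenchmark":
        """Curate a raw cohort (impossible values, sparsity, median centring,
        complete cases) and benchmark on the resulting complete cases."""
        cc, _, _ = curate(cohort, mode=correction_mode, max_col_missing=max_col_missing)
        return cls.from_cohort(cc, config)

    def fit(self, master_seed: int | None = None) -> "BenchmarkResults":
        config = (
            replace(self.config, master_seed=master_seed)
            if master_seed is not None
            else self.config
        )
        records = run_grid(self.X, self.Y, self.C, config)
        return BenchmarkResults(self, config, records)


class BenchmarkResults:
    """Results of a fitted benchmark: records, aggregates, rankings."""

    def __init__(
        self, model: ImputationBenchmark, config: ExperimentConfig, records: pd.DataFrame
    ) -> None:
        self.model = model
        self.config = config
        self.records = records
        self._aggregated: pd.DataFrame | None = None

    def aggregate(self) -> pd.DataFrame:
        if self._aggregated is None:
            self._aggregated = aggregate(self.records)
        return self._aggregated

    def rank_table(self) -> pd.DataFrame:
        return rank_strategies(self.aggregate())

    # --- headline comparisons -------------------------------------------

    def engine_comparison(self) -> pd.DataFrame:
        """Per condition: best mean full MAE of each engine."""
        agg = self.aggregate()
        ok = agg[agg["failure_fraction"] == 0.0]
        rows = []
        for cell, grp in ok.groupby(["sample_size", "mechanism", "proportion"]):
            row = dict(zip(["sample_size", "mechanism", "proportion"], cell))
            for eng, label in (("missForest", "missforest"), ("MICErf", "micerf")):
                sub = grp[grp["strategy"].str.startswith(eng)]
                row[f"best_{label}_mae"] = sub["mae_full_mean"].min() if len(sub) else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def fraction_missforest_best(self) -> float:
        """Fraction of grid cells where the best iterative-engine strategy
        has mean full MAE <= the best chained-engine strategy."""
        cmp = self.engine_comparison().dropna()
        return float((cmp["best_missforest_mae"] <= cmp["best_micerf_mae"]).mean())

    def fraction_stratified_micerf_worst(self) -> float:
        """Fraction of grid cells where a stratified chained-engine strategy
        ranks worst among the chained-engine strategies (failed runs count
        as worst)."""
        agg = self.aggregate()
        hits, cells = 0, 0
        for _, grp in agg.groupby(["sample_size", "mechanism", "proportion"]):
            mice = grp[grp["strategy"].str.startswith("MICErf")]
            if mice.empty:
                continue
            cells += 1
            failed_strata = mice[(mice["failure_fraction"] > 0)]
            if len(failed_strata) and failed_strata["strategy"].str.contains("Strata").any():
                hits += 1
                continue
            worst = mice.sort_values("mae_full_mean").iloc[-1]
            if "Strata" in worst["strategy"]:
                hits += 1
        return hits / cells if cells else float("nan")

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            "Imputation strategy benchmark",
            "=============================",
            f"cohort rows: {len(self.model.X)}, analytes: {self.model.X.shape[1]}",
            f"grid: {len(self.config.sample_sizes)} sample size(s) x "
            f"{len(self.config.mechanisms)} mechanisms x "
            f"{len(self.config.proportions)} proportions x "
            f"{len(self.config.strategies)} strategies x "
            f"{self.config.repetitions} repetitions",
            f"records: {len(self.records)} "
            f"(failed: {int(self.records['failed'].sum())})",
            "",
            f"cells where best missForest <= best MICErf (full MAE): "
            f"{self.fraction_missforest_best():.2f}",
            f"cells where stratified MICErf is the worst MICErf variant: "
            f"{self.fraction_stratified_micerf_worst():.2f}",
            "",
            "top strategy per (mechanism, proportion), largest N:",
        ]
        n_max = max(self.config.sample_sizes)
        ranks = self.rank_table()
        top = ranks[(ranks["rank"] == 1) & (ranks["sample_size"] == n_max)]
        for _, row in top.iterrows():
            lines.append(
                f"  {row['mechanism']:4s} M={row['proportion']:.2f}: "
                f"{row['strategy']} (full MAE {row['mae_full_mean']:.4f})"
            )
        return "\n".join(lines)

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.aggregate().to_csv(out / "aggregate.csv", index=False)
        self.rank_table().to_csv(out / "ranks.csv", index=False)
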