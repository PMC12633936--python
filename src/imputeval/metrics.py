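"""Imputation performance metrics.

Internal metrics score imputed values against the held-back truth at the
masked cells:

NRMSE
    ``sqrt(mean((true - imputed)^2) / var(true))`` over masked cells, with
    the population variance convention, so imputing every masked cell with
    the mean of the masked true values scores exactly 1 and a perfect
    imputation scores 0.
MAE
    *partial*: per-analyte mean absolute error at that analyte's masked
    cells, in raw units. *full*: all masked cells pooled after dividing each
    analyte's absolute errors by the analyte's truth standard deviation
    (analytes have incommensurate units); a ``raw`` pooling switch is
    provided.

External metrics compare downstream structure:

relationship bias
    absolute error of the least-squares slope of a known linear analyte
    pair, for the imputed data and for the complete-case (not-imputing)
    baseline, both against the slope fitted on the full truth.
distribution shift
    two-sample Kolmogorov-Smirnov statistic between an analyte's truth and
    post-imputation columns (0 identical, 1 disjoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .cohort import RelationshipPair

__all__ = [
    "MetricError",
    "nrmse",
    "mae",
    "relationship_bias",
    "distribution_shift",
]


class MetricError(ValueError):
    pass


def _as_arrays(
    X_true: pd.DataFrame | np.ndarray,
    X_imputed: pd.DataFrame | np.ndarray,
    mask: pd.DataFrame | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.asarray(X_true, dtype=float)
    i = np.asarray(X_imputed, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if not (t.shape == i.shape == m.shape):
        raise MetricError("shape-mismatch: truth, imputation and mask must align")
    return t, i, m


def nrmse(X_true, X_imputed, mask) -> float:
    """Normalised root mean squared error at the masked cells."""
    t, i, m = _as_arrays(X_true, X_imputed, mask)
    if not m.any():
        raise MetricError("no-missing-cells")
    err = t[m] - i[m]
    var = t[m].var()  # population convention (ddof=0)
    if var == 0:
        raise MetricError("nrmse-undefined: zero truth variance at masked cells")
    return float(np.sqrt((err**2).mean() / var))


def mae(X_true, X_imputed, mask, scope: str = "full", pooling: str = "sd"):
    """Mean absolute error at the masked cells.

    ``scope='partial'`` returns a per-analyte Series (analytes with no
    masked cells are absent, not zero); ``scope='full'`` pools every masked
    cell after per-analyte scale harmonisation (``pooling='sd'``, the
    default) or without it (``pooling='raw'``).
    """
    if scope not in ("full", "partial"):
        raise MetricError(f"unknown scope: {scope}")
    if pooling not in ("sd", "raw"):
        raise MetricError(f"unknown pooling: {pooling}")
    t, i, m = _as_arrays(X_true, X_imputed, mask)
    if not m.any():
        raise MetricError("no-missing-cells")
    columns = (
        list(X_true.columns) if isinstance(X_true, pd.DataFrame) else list(range(t.shape[1]))
    )
    if scope == "partial":
        vals = {}
        for j, c in enumerate(columns):
            mj = m[:, j]
            if mj.any():
                vals[c] = float(np.abs(t[mj, j] - i[mj, j]).mean())
        return pd.Series(vals)
    abs_err = np.abs(t - i)
    if pooling == "sd":
        sds = t.std(axis=0, ddof=0)
        if (sds[m.any(axis=0)] == 0).any():
            raise MetricError("mae-undefined: zero truth SD for a masked analyte")
        abs_err = abs_err / sds
    return float(abs_err[m].mean())


def _slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.size < 3:
        raise MetricError("fit-undefined: fewer than 3 rows for the slope fit")
    if np.ptp(x) == 0:
        raise MetricError("fit-undefined: degenerate predictor")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def relationship_bias(
    X_true: pd.DataFrame,
    X_imputed: pd.DataFrame,
    mask: pd.DataFrame,
    pair: RelationshipPair,
) -> dict[str, float]:
    """Slope bias of a known linear pair, imputed versus not imputing.

    The reference slope is fitted on the full truth (usable on real data,
    where the planted slope is unknown). The not-imputing baseline refits on
    the rows where both pair columns are observed (complete-case analysis).
    """
    for col in (pair.response, pair.predictor):
        if col not in X_true.columns:
            raise MetricError(f"fit-undefined: column '{col}' absent")
    xt = X_true[pair.predictor].to_numpy(dtype=float)
    yt = X_true[pair.response].to_numpy(dtype=float)
    beta_true, alpha_true = _slope(xt, yt)

    xi = X_imputed[pair.predictor].to_numpy(dtype=float)
    yi = X_imputed[pair.response].to_numpy(dtype=float)
    beta_imp, alpha_imp = _slope(xi, yi)

    m = np.asarray(mask[[pair.predictor, pair.response]], dtype=bool)
    cca_rows = ~m.any(axis=1)
    beta_cca, alpha_cca = _slope(xt[cca_rows], yt[cca_rows])

    return {
        "slope_error_imputed": abs(beta_imp - beta_true),
        "slope_error_cca": abs(beta_cca - beta_true),
        "intercept_error_imputed": abs(alpha_imp - alpha_true),
        "intercept_error_cca": abs(alpha_cca - alpha_true),
    }


def distribution_shift(true_column, imputed_column) -> float:
    """Two-sample KS statistic between truth and post-imputation values."""
    t = np.asarray(true_column, dtype=float)
    i = np.asarray(imputed_column, dtype=float)
    if t.size < 2 or i.size < 2:
        raise MetricError("insufficient-data")
    return float(ks_2samp(t, i).statistic)
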