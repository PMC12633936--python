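"""Controlled amputation: MCAR, MAR and MNAR missingness at exact proportions.

Given a complete analyte block, a mask of exactly ``round(M * n * p)`` cells
is drawn. The global count is split across columns as evenly as possible
(remainder cells assigned to a seeded random subset of columns) so no column
is accidentally emptied. Within a column the mechanisms differ:

MCAR
    rows drawn uniformly without replacement.
MAR
    deletion probability proportional to the rank of a *driver* column's
    value in the same row (drivers assigned cyclically: column j is driven
    by column j+1 mod p, unless a driver map is supplied).
MNAR
    deletion probability proportional to the rank of the column's own value,
    so high values are preferentially deleted.

Selection probabilities are computed from the complete pre-amputation
matrix, as is standard for amputation studies, so a deletion decision never
depends on information the mask itself removes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._seeds import derive_seed

__all__ = ["Mask", "make_mask", "apply_mask", "MECHANISMS", "DEFAULT_PROPORTIONS"]

MECHANISMS = ("MCAR", "MAR", "MNAR")
#: The evaluation's proportion grid: 5, 10, 20, 30 and 40% missingness.
DEFAULT_PROPORTIONS = (0.05, 0.10, 0.20, 0.30, 0.40)


@dataclass
class Mask:
    """A boolean missingness pattern aligned to an analyte block."""

    pattern: pd.DataFrame  # bool, True = missing
    mechanism: str
    proportion: float
    seed: int
    driver_map: dict[str, str] = field(default_factory=dict)

    @property
    def n_missing(self) -> int:
        return int(self.pattern.to_numpy().sum())

    def content_hash(self) -> str:
        """Stable hash of the pattern, used to verify paired designs."""
        import hashlib

        return hashlib.blake2b(
            np.packbits(self.pattern.to_numpy()).tobytes(), digest_size=8
        ).hexdigest()

    def to_files(self, cells_path: str | Path, header_path: str | Path) -> None:
        r, c = np.nonzero(self.pattern.to_numpy())
        pd.DataFrame(
            {"sample_id": self.pattern.index[r], "analyte": self.pattern.columns[c]}
        ).to_csv(cells_path, index=False)
        Path(header_path).write_text(
            json.dumps(
                {
                    "mechanism": self.mechanism,
                    "proportion": self.proportion,
                    "seed": self.seed,
                    "driver_map": self.driver_map,
                }
            )
        )

    @classmethod
    def from_files(
        cls, cells_path: str | Path, header_path: str | Path, like: pd.DataFrame
    ) -> "Mask":
        header = json.loads(Path(header_path).read_text())
        cells = pd.read_csv(cells_path)
        pattern = pd.DataFrame(False, index=like.index, columns=like.columns)
        for sid, a in zip(cells["sample_id"], cells["analyte"]):
            pattern.loc[sid, a] = True
        return cls(pattern=pattern, **header)


def _column_quotas(n: int, p: int, total: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` cells across p columns as evenly as possible."""
    base, rem = divmod(total, p)
    quotas = np.full(p, base, dtype=int)
    if rem:
        quotas[rng.permutation(p)[:rem]] += 1
    if (quotas > n).any():
        raise ValueError("proportion-out-of-range: a column quota exceeds the row count")
    return quotas


def make_mask(
    X: pd.DataFrame,
    mechanism: str,
    proportion: float,
    seed: int,
    driver_map: dict[str, str] | None = None,
) -> Mask:
    """Draw a missingness mask over a complete analyte block.

    The total number of masked cells is exactly ``round(proportion * n * p)``
    and the draw is deterministic given ``seed``.
    """
    mechanism = mechanism.upper()
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism: {mechanism}")
    if not 0.0 < proportion < 1.0:
        raise ValueError("proportion-out-of-range: proportion must lie in (0, 1)")
    if X.isna().any().any():
        raise ValueError("X must be complete before amputation")
    n, p = X.shape
    if mechanism == "MAR" and p < 2 and not driver_map:
        raise ValueError("driver-unassignable: MAR needs a second column as driver")

    rng = np.random.default_rng(derive_seed("mask", mechanism, proportion, seed))
    total = round(proportion * n * p)
    quotas = _column_quotas(n, p, total, rng)

    columns = list(X.columns)
    if mechanism == "MAR":
        drivers = driver_map or {
            columns[j]: columns[(j + 1) % p] for j in range(p)
        }
        unknown = set(drivers.values()) - set(columns)
        if unknown:
            raise ValueError(f"driver-unassignable: unknown driver columns {unknown}")
    else:
        drivers = {}

    values = X.to_numpy(dtype=float)
    pattern = np.zeros((n, p), dtype=bool)
    for j, col in enumerate(columns):
        q = quotas[j]
        if q == 0:
            continue
        if mechanism == "MCAR":
            rows = rng.choice(n, size=q, replace=False)
        else:
            src = columns.index(drivers[col]) if mechanism == "MAR" else j
            ranks = rankdata(values[:, src])
            probs = ranks / ranks.sum()
            rows = rng.choice(n, size=q, replace=False, p=probs)
        pattern[rows, j] = True

    return Mask(
        pattern=pd.DataFrame(pattern, index=X.index, columns=X.columns),
        mechanism=mechanism,
        proportion=proportion,
        seed=seed,
        driver_map=drivers,
    )


def apply_mask(X: pd.DataFrame, mask: Mask) -> pd.DataFrame:
    """Return a copy of X with masked cells set missing.

    Unmasked cells are bit-identical to the input; the input itself is never
    modified (it remains the ground truth for scoring).
    """
    if X.shape != mask.pattern.shape or not X.index.equals(mask.pattern.index):
        raise ValueError("shape-mismatch: mask is not aligned to X")
    return X.mask(mask.pattern)
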