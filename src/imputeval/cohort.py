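"""Synthetic multi-centre preclinical cohort generator.

Emulates the structure of a large multi-site rat toxicology study: a number
of single-toxin studies, each with 30 animals split into control (animals
1-10), low-dose (11-20) and high-dose (21-30) groups, and exactly two serum
samples per animal -- one at 24 h and a second at either 48 h or 168 h.
Serum clinical-chemistry analytes are positive and right-skewed (log-normal
marginals), share a mild exchangeable correlation, and carry planted
high-correlation linear pairs (e.g. ALT~AST) whose squared correlation is
controlled exactly. Each study adds an additive per-(study, analyte) batch
shift, the signal that median-centring batch correction removes.

The generated table is the ground truth for the whole evaluation: masks are
cut from it, imputations are scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import derive_seed

__all__ = [
    "RelationshipPair",
    "CohortSpec",
    "CohortTable",
    "TruthSummary",
    "generate_cohort",
    "truth_summary",
    "write_cohort",
    "read_cohort",
    "DEFAULT_ANALYTES",
]

#: Default serum clinical-chemistry panel (12 analytes).
DEFAULT_ANALYTES: tuple[str, ...] = (
    "ALT",
    "AST",
    "Creatinine",
    "Urea_Nitrogen",
    "ALP",
    "GGT",
    "Glucose",
    "Cholesterol",
    "Triglycerides",
    "Total_Protein",
    "Albumin",
    "Total_Bilirubin",
)

# Log-scale (mu, sigma) of the log-normal marginals, loosely matching rat
# serum reference ranges (units arbitrary but fixed per analyte).
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "ALT": (3.8, 0.35),
    "AST": (4.5, 0.30),  # overridden when AST is a planted response
    "Creatinine": (-0.8, 0.25),
    "Urea_Nitrogen": (2.7, 0.30),
    "ALP": (5.3, 0.40),
    "GGT": (0.0, 0.45),
    "Glucose": (4.9, 0.20),
    "Cholesterol": (4.2, 0.30),
    "Triglycerides": (4.4, 0.45),
    "Total_Protein": (1.9, 0.10),
    "Albumin": (1.3, 0.12),
    "Total_Bilirubin": (-1.9, 0.35),
}

_ORGANS = ("liver", "kidney", "heart", "muscle", "pancreas", "gi_tract")

Y_COLUMNS = ("timepoint_h", "dose_group", "target_organ", "toxin", "euthanasia_group")


@dataclass(frozen=True)
class RelationshipPair:
    """A planted linear relationship ``response = slope*predictor + intercept + noise``.

    ``target_r2`` is the squared Pearson correlation the generated pair
    should exhibit across the whole cohort (batch shifts included).
    """

    response: str
    predictor: str
    slope: float
    intercept: float
    target_r2: float

    def __post_init__(self) -> None:
        if self.response == self.predictor:
            raise ValueError("spec-invalid: response and predictor must differ")
        if not 0.0 < self.target_r2 < 1.0:
            raise ValueError("spec-invalid: target_r2 must lie strictly in (0, 1)")

    @property
    def label(self) -> str:
        return f"{self.response}~{self.predictor}"


DEFAULT_PAIRS: tuple[RelationshipPair, ...] = (
    RelationshipPair("AST", "ALT", slope=1.1, intercept=40.0, target_r2=0.86),
    RelationshipPair("Urea_Nitrogen", "Creatinine", slope=20.0, intercept=6.0, target_r2=0.72),
)


@dataclass(frozen=True)
class CohortSpec:
    """Design parameters of a synthetic multi-centre cohort."""

    n_studies: int = 107
    animals_per_study: int = 30
    companies: tuple[str, ...] = ("A", "B", "C", "D", "E")
    timepoints_h: tuple[int, ...] = (24, 48, 168)
    dose_groups: tuple[str, ...] = ("control", "low", "high")
    analytes: tuple[str, ...] = DEFAULT_ANALYTES
    relationship_pairs: tuple[RelationshipPair, ...] = DEFAULT_PAIRS
    #: Per-study additive shift scale, relative to each analyte's marginal SD.
    batch_shift_scale: float = 0.2
    #: Log-scale (mu, sigma) per analyte; defaults filled from DEFAULT_MARGINALS.
    marginals: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: Exchangeable latent correlation among non-pair analytes.
    exchangeable_rho: float = 0.2
    #: Multiplicative high/low-dose perturbation on a subset of analytes.
    dose_effect_analytes: tuple[str, ...] = ("Glucose", "ALP", "Total_Bilirubin")
    dose_effect_high: float = 1.4
    dose_effect_low: float = 1.15
    toxin_levels: int = 107
    #: Optional explicit study -> company allocation; default is round-robin.
    studies_per_company: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.animals_per_study < 1 or self.toxin_levels < 1:
            raise ValueError("spec-invalid: counts must be positive")
        if self.animals_per_study % len(self.dose_groups):
            raise ValueError("spec-invalid: animals_per_study must split evenly across dose groups")
        if len(set(self.analytes)) != len(self.analytes):
            raise ValueError("spec-invalid: analyte names must be unique")
        for pair in self.relationship_pairs:
            if pair.response not in self.analytes or pair.predictor not in self.analytes:
                raise ValueError(f"spec-invalid: unknown analyte in pair {pair.label}")

    def marginal(self, analyte: str) -> tuple[float, float]:
        if analyte in self.marginals:
            return self.marginals[analyte]
        if analyte in DEFAULT_MARGINALS:
            return DEFAULT_MARGINALS[analyte]
        return (3.0, 0.3)

    @property
    def n_samples(self) -> int:
        return self.n_studies * self.animals_per_study * 2


@dataclass
class CohortTable:
    """A samples-by-analytes block ``X`` plus row metadata.

    ``X`` holds the continuous analytes (index = sample_id); ``meta`` holds
    the design columns (study_id, animal_number, company and the Y block).
    """

    X: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.meta.index):
            raise ValueError("alignment-error: X and meta must share a row index")
        if self.X.columns.duplicated().any():
            raise ValueError("spec-invalid: duplicate analyte columns")

    @property
    def Y(self) -> pd.DataFrame:
        """Metadata block used as imputation features (excludes company)."""
        return self.meta[list(Y_COLUMNS)]

    @property
    def C(self) -> pd.Series:
        """Outcome/centre variable: the company label per row."""
        return self.meta["company"]

    @property
    def is_control(self) -> pd.Series:
        return self.meta["dose_group"] == "control"

    def copy(self) -> "CohortTable":
        return CohortTable(self.X.copy(), self.meta.copy())

    def __len__(self) -> int:
        return len(self.X)


def _solve_noise_sd(pair: RelationshipPair, var_pred: float, shift_scale: float) -> float:
    """Noise SD achieving ``target_r2`` under relative batch-shift scale c.

    With independent additive shifts of variance c^2 * Var on both members,
    the observable squared correlation is
    r2 = a^2 Vx / ((1+c^2)^2 (a^2 Vx + s^2)), hence
    s^2 = a^2 Vx (1/((1+c^2)^2 r2) - 1); infeasible when the bound
    1/(1+c^2)^2 falls below the target.
    """
    c2 = shift_scale**2
    bound = 1.0 / (1.0 + c2) ** 2
    if pair.target_r2 >= bound:
        raise ValueError(
            f"spec-infeasible: target_r2={pair.target_r2} for {pair.label} exceeds the "
            f"attainable bound {bound:.4f} at batch_shift_scale={shift_scale}"
        )
    var_noise = pair.slope**2 * var_pred * (1.0 / ((1.0 + c2) ** 2 * pair.target_r2) - 1.0)
    return float(np.sqrt(var_noise))


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Generate a complete (no missing cells) synthetic cohort.

    Deterministic given ``spec.seed``; all analyte values are strictly
    positive.
    """
    rng = np.random.default_rng(derive_seed("cohort", spec.seed))
    n_per_dose = spec.animals_per_study // len(spec.dose_groups)
    studies = np.arange(1, spec.n_studies + 1)

    # --- design / metadata rows ------------------------------------------
    rows: list[tuple] = []
    for s in studies:
        company = (
            _company_for_study(s, spec)
            if spec.studies_per_company
            else spec.companies[(s - 1) % len(spec.companies)]
        )
        toxin = f"toxin_{1 + (s - 1) % spec.toxin_levels:03d}"
        organ = _ORGANS[(s - 1) % len(_ORGANS)]
        for animal in range(1, spec.animals_per_study + 1):
            dose = spec.dose_groups[(animal - 1) // n_per_dose]
            # second-timepoint allocation alternates by animal parity
            late = 48 if animal % 2 == 1 else 168
            euth = f"{late}h"
            for tp in (24, late):
                sid = f"S{s:03d}_A{animal:02d}_T{tp:03d}"
                rows.append((sid, s, animal, tp, dose, organ, toxin, euth, company))
    meta = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "study_id",
            "animal_number",
            "timepoint_h",
            "dose_group",
            "target_organ",
            "toxin",
            "euthanasia_group",
            "company",
        ],
    ).set_index("sample_id")
    n = len(meta)
    study_idx = meta["study_id"].to_numpy() - 1

    # --- analyte block ----------------------------------------------------
    pair_responses = {p.response for p in spec.relationship_pairs}
    base_analytes = [a for a in spec.analytes if a not in pair_responses]

    # exchangeable Gaussian copula for the base analytes
    common = rng.standard_normal(n)
    rho = spec.exchangeable_rho
    values: dict[str, np.ndarray] = {}
    for a in base_analytes:
        mu, sigma = spec.marginal(a)
        z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        values[a] = np.exp(mu + sigma * z)

    # planted linear responses
    for pair in spec.relationship_pairs:
        mu_p, sigma_p = spec.marginal(pair.predictor)
        var_pred = (np.exp(sigma_p**2) - 1.0) * np.exp(2 * mu_p + sigma_p**2)
        noise_sd = _solve_noise_sd(pair, var_pred, spec.batch_shift_scale)
        pred = values[pair.predictor]
        values[pair.response] = pair.slope * pred + pair.intercept + noise_sd * rng.standard_normal(n)

    X = np.column_stack([values[a] for a in spec.analytes])

    # dose effects (multiplicative, on the configured subset)
    if spec.dose_effect_analytes:
        dose = meta["dose_group"].to_numpy()
        for a in spec.dose_effect_analytes:
            j = spec.analytes.index(a)
            X[dose == "high", j] *= spec.dose_effect_high
            X[dose == "low", j] *= spec.dose_effect_low

    # additive per-(study, analyte) batch shifts, identical within a study
    if spec.batch_shift_scale > 0:
        sds = X.std(axis=0, ddof=0)
        shifts = rng.normal(0.0, spec.batch_shift_scale, size=(spec.n_studies, len(spec.analytes))) * sds
        X = X + shifts[study_idx, :]

    # positivity guard: the defaults make non-positive draws essentially
    # impossible; extreme user configs are clipped to a tiny positive value
    np.maximum(X, 1e-9, out=X)

    Xdf = pd.DataFrame(X, index=meta.index, columns=list(spec.analytes))
    return CohortTable(Xdf, meta)


def _company_for_study(s: int, spec: CohortSpec) -> str:
    alloc = spec.studies_per_company or {}
    if sum(alloc.values()) != spec.n_studies:
        raise ValueError("spec-invalid: studies_per_company must sum to n_studies")
    bound = 0
    for company in spec.companies:
        bound += alloc.get(company, 0)
        if s <= bound:
            return company
    raise ValueError("spec-invalid: study allocation exhausted")


@dataclass
class TruthSummary:
    """Ground-truth summaries recomputed directly from a complete table."""

    control_medians: pd.DataFrame  # study x analyte, controls at all timepoints
    grand_median: pd.Series  # per analyte, 24-h controls pooled
    r2_matrix: pd.DataFrame  # analyte x analyte squared Pearson correlation
    pair_fits: dict[str, dict[str, float]]  # label -> slope/intercept/r2


def truth_summary(table: CohortTable, pairs: tuple[RelationshipPair, ...] = ()) -> TruthSummary:
    """Summaries for validating the generator; requires a complete table."""
    if table.X.isna().any().any():
        raise ValueError("incomplete-input: table has missing cells")
    ctrl = table.is_control
    ctrl_X = table.X[ctrl]
    ctrl_meta = table.meta[ctrl]
    control_medians = ctrl_X.groupby(ctrl_meta["study_id"]).median()
    at24 = ctrl & (table.meta["timepoint_h"] == 24)
    grand_median = table.X[at24].median()
    corr = table.X.corr()
    r2_matrix = corr**2
    fits = {}
    for pair in pairs:
        x = table.X[pair.predictor].to_numpy()
        y = table.X[pair.response].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        fits[pair.label] = {"slope": float(slope), "intercept": float(intercept), "r2": r2}
    return TruthSummary(control_medians, grand_median, r2_matrix, fits)


def write_cohort(table: CohortTable, x_path: str | Path, meta_path: str | Path) -> None:
    """Write the analyte block and metadata as two CSVs sharing sample_id."""
    table.X.to_csv(x_path, index_label="sample_id")
    table.meta.to_csv(meta_path, index_label="sample_id")


def read_cohort(x_path: str | Path, meta_path: str | Path) -> CohortTable:
    X = pd.read_csv(x_path, index_col="sample_id")
    meta = pd.read_csv(meta_path, index_col="sample_id")
    return CohortTable(X, meta.loc[X.index])


def spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a plain (YAML/JSON-loaded) mapping."""
    d = dict(d)
    if "relationship_pairs" in d:
        d["relationship_pairs"] = tuple(
            RelationshipPair(**p) if isinstance(p, dict) else p for p in d["relationship_pairs"]
        )
    for key in ("companies", "timepoints_h", "dose_groups", "analytes", "dose_effect_analytes"):
        if key in d:
            d[key] = tuple(d[key])
    return CohortSpec(**d)
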