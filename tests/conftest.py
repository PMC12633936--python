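import numpy as np
import pandas as pd
import pytest

from imputeval import CohortSpec, CohortTable, curate, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> CohortTable:
    """Full-size synthetic cohort (107 studies x 30 animals x 2 samples)."""
    return generate_cohort(CohortSpec(seed=3))


@pytest.fixture(scope="session")
def complete_table(default_cohort) -> CohortTable:
    """Curated complete-case table derived from the default cohort."""
    cc, _, _ = curate(default_cohort)
    return cc


def build_table(
    X: dict[str, list[float]],
    study_id: list[int],
    animal_number: list[int],
    timepoint_h: list[int],
    company: list[str] | None = None,
) -> CohortTable:
    """Hand-crafted CohortTable for toy curation/metrics scenarios."""
    n = len(study_id)
    idx = pd.Index([f"row{i:02d}" for i in range(n)], name="sample_id")
    xdf = pd.DataFrame(X, index=idx, dtype=float)
    dose = ["control" if a <= 10 else ("low" if a <= 20 else "high") for a in animal_number]
    meta = pd.DataFrame(
        {
            "study_id": study_id,
            "animal_number": animal_number,
            "timepoint_h": timepoint_h,
            "dose_group": dose,
            "target_organ": ["liver"] * n,
            "toxin": [f"toxin_{s:03d}" for s in study_id],
            "euthanasia_group": ["48h"] * n,
            "company": company or ["A"] * n,
        },
        index=idx,
    )
    return CohortTable(xdf, meta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
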