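"""Curation chain: impossible values, sparsity filters, median centring."""

import numpy as np
import pandas as pd
import pytest

from imputeval import (
    apply_correction,
    complete_cases,
    curate,
    drop_sparse,
    fit_median_centring,
    remove_impossible,
)
from imputeval.curation import CorrectionModel, CurationError

from conftest import build_table


def toy_table(values: dict[str, list[float]]) -> "CohortTable":
    n = len(next(iter(values.values())))
    return build_table(
        X=values,
        study_id=[1] * n,
        animal_number=list(range(1, n + 1)),
        timepoint_h=[24] * n,
    )


class TestRemoveImpossible:
    def test_negative_cell_masked_and_logged(self):
        table = toy_table({"ALT": [1.0, -3.1, 2.0]})
        out, log = remove_impossible(table)
        assert np.isnan(out.X.iloc[1, 0])
        assert log.cells_set_missing == [("row01", "ALT", "negative")]

    def test_clean_table_is_identity(self):
        table = toy_table({"ALT": [1.0, 2.0], "AST": [3.0, 4.0]})
        out, log = remove_impossible(table)
        pd.testing.assert_frame_equal(out.X, table.X)
        assert log.to_frame().empty

    def test_log_count_matches_independent_scan(self, rng):
        vals = rng.normal(5, 3, size=(20, 5))
        vals[(3, 1)] = -1.0
        vals[(7, 4)] = -2.5
        vals = np.abs(vals)
        vals[3, 1], vals[7, 4] = -1.0, -2.5
        table = toy_table({f"A{j}": vals[:, j].tolist() for j in range(5)})
        _, log = remove_impossible(table)
        assert len(log.cells_set_missing) == int((vals < 0).sum()) == 2


class TestDropSparse:
    def test_column_above_threshold_dropped(self):
        col = [np.nan] * 5 + [1.0] * 5  # 50% missing
        table = toy_table({"A": col, "B": [1.0] * 10})
        out, log = drop_sparse(table, max_col_missing=0.40)
        assert list(out.X.columns) == ["B"]
        assert ("A", "mostly-missing") in log.removed_columns

    def test_boundary_column_retained(self):
        col = [np.nan] * 4 + [1.0] * 6  # exactly 40% missing
        table = toy_table({"A": col})
        out, _ = drop_sparse(table, max_col_missing=0.40)
        assert "A" in out.X.columns

    def test_toy_6x3_table(self):
        # one empty row (row05) and one 50%-missing column (B) -> 5 x 2
        table = toy_table(
            {
                "A": [1, 2, 3, 4, 5, np.nan],
                "B": [1, np.nan, np.nan, np.nan, 5, np.nan],
                "C": [1, 2, 3, 4, 5, np.nan],
            }
        )
        out, log = drop_sparse(table, max_col_missing=0.40)
        assert out.X.shape == (5, 2)
        assert list(out.X.columns) == ["A", "C"]
        assert ("row05", "empty") in log.removed_rows

    def test_all_columns_removed_raises(self):
        table = toy_table({"A": [np.nan, np.nan, 1.0]})
        with pytest.raises(CurationError, match="empty-after-filter"):
            drop_sparse(table, max_col_missing=0.10)


class TestMedianCentring:
    def test_grand_median_pools_24h_controls(self):
        table = build_table(
            X={"ALT": [1.0, 3.0, 5.0, 7.0]},
            study_id=[1, 1, 2, 2],
            animal_number=[1, 2, 1, 2],
            timepoint_h=[24, 24, 24, 24],
        )
        model = fit_median_centring(table)
        assert model.gm["ALT"] == 4.0

    def test_study_median_uses_all_timepoints(self):
        table = build_table(
            X={"ALT": [2.0, 2.0, 2.0]},
            study_id=[1, 1, 1],
            animal_number=[1, 1, 2],
            timepoint_h=[24, 48, 24],
        )
        model = fit_median_centring(table)
        assert model.sm.loc[1, "ALT"] == 2.0

    @pytest.mark.parametrize(
        "mode,x,expected",
        [("shift", 10.0, 7.0), ("ratio", 10.0, 6.25)],
    )
    def test_correction_arithmetic(self, mode, x, expected):
        # SM = 8 (study controls), GM = 5 (24h controls of the other study)
        table = build_table(
            X={"ALT": [8.0, 8.0, 5.0, 5.0, x]},
            study_id=[1, 1, 2, 2, 1],
            animal_number=[1, 2, 1, 2, 21],
            timepoint_h=[48, 48, 24, 24, 24],
        )
        model = fit_median_centring(table, mode=mode)
        assert model.sm.loc[1, "ALT"] == 8.0 and model.gm["ALT"] == 5.0
        out, _ = apply_correction(table, model)
        assert out.X.loc["row04", "ALT"] == pytest.approx(expected)

    def test_shift_to_negative_masks_and_logs(self):
        table = build_table(
            X={"ALT": [9.0, 9.0, 5.0, 5.0, 1.0]},
            study_id=[1, 1, 2, 2, 1],
            animal_number=[1, 2, 1, 2, 21],
            timepoint_h=[48, 48, 24, 24, 24],
        )
        model = fit_median_centring(table)  # SM=9, GM=5, shift=4 -> 1-4=-3
        out, log = apply_correction(table, model)
        assert np.isnan(out.X.loc["row04", "ALT"])
        assert ("row04", "ALT", "negative-after-correction") in log.cells_set_missing

    def test_zero_shift_when_sm_equals_gm(self):
        table = build_table(
            X={"ALT": [5.0, 5.0, 3.0]},
            study_id=[1, 1, 1],
            animal_number=[1, 2, 21],
            timepoint_h=[24, 24, 24],
        )
        model = fit_median_centring(table)
        out, _ = apply_correction(table, model)
        pd.testing.assert_frame_equal(out.X, table.X)

    def test_control_medians_align_to_gm_after_shift(self, default_cohort):
        model = fit_median_centring(default_cohort)
        corrected, log = apply_correction(default_cohort, model)
        ctrl = corrected.is_control
        med = corrected.X[ctrl].groupby(corrected.meta.loc[ctrl, "study_id"]).median()
        dev = (med - model.gm).abs()
        # medians are shift-equivariant, so alignment is exact up to float
        # rounding -- except where a control cell was masked for turning
        # negative, which legitimately moves that study's median
        touched = {
            (default_cohort.meta.loc[sid, "study_id"], analyte)
            for sid, analyte, _ in log.cells_set_missing
        }
        for study in dev.index:
            for analyte in dev.columns:
                if (study, analyte) not in touched:
                    assert dev.loc[study, analyte] < 1e-9

    def test_shift_correction_round_trips(self, default_cohort):
        model = fit_median_centring(default_cohort)
        corrected, _ = apply_correction(default_cohort, model)
        shift = (model.sm - model.gm).loc[corrected.meta["study_id"]].to_numpy()
        recovered = corrected.X.to_numpy() + shift
        original = default_cohort.X.to_numpy()
        ok = ~np.isnan(corrected.X.to_numpy())  # cells that stayed non-negative
        assert np.allclose(recovered[ok], original[ok], rtol=0, atol=1e-12)

    def test_ratio_zero_sm_logged(self):
        table = build_table(
            X={"ALT": [0.0, 0.0, 2.0, 2.0, 4.0]},
            study_id=[1, 1, 2, 2, 1],
            animal_number=[1, 2, 1, 2, 21],
            timepoint_h=[24, 24, 24, 24, 24],
        )
        model = fit_median_centring(table, mode="ratio")
        out, log = apply_correction(table, model)
        # uncorrectable cells are left untouched
        assert out.X.loc["row04", "ALT"] == 4.0
        assert any(r == "ratio-undefined" for _, _, r in log.cells_set_missing)


class TestCompleteCases:
    def test_rows_with_missing_dropped(self):
        table = toy_table({"A": [1, np.nan, 3, 4, 5], "B": [1, 2, np.nan, 4, 5]})
        out = complete_cases(table)
        assert len(out) == 3
        assert list(out.X.index) == ["row00", "row03", "row04"]

    def test_complete_table_identity(self):
        table = toy_table({"A": [1.0, 2.0]})
        pd.testing.assert_frame_equal(complete_cases(table).X, table.X)

    def test_no_complete_cases_raises(self):
        table = toy_table({"A": [np.nan, 1.0], "B": [1.0, np.nan]})
        with pytest.raises(CurationError, match="no-complete-cases"):
            complete_cases(table)

    def test_agrees_with_curation_log(self):
        table = toy_table({"A": [1.0, -2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        cleaned, log = remove_impossible(table)
        cc = complete_cases(cleaned)
        flagged_rows = {sid for sid, _, _ in log.cells_set_missing}
        assert set(table.X.index) - set(cc.X.index) == flagged_rows


class TestPipelineOrder:
    def test_canonical_order_output(self):
        # a table where running complete-cases before the negativity rule
        # would keep row02 (whose negative cell only appears after masking)
        table = build_table(
            X={
                "A": [6.0, 6.0, 4.0, 4.0, -1.0, 10.0],
                "B": [2.0, 2.0, 2.0, 2.0, 2.0, np.nan],
            },
            study_id=[1, 1, 2, 2, 1, 1],
            animal_number=[1, 2, 1, 2, 21, 22],
            timepoint_h=[24, 24, 24, 24, 24, 24],
        )
        cc, model, log = curate(table, max_col_missing=0.5)
        # canonical: -1 masked first, so row04 is not a complete case
        assert "row04" not in cc.X.index
        assert ("row04", "A", "negative") in log.cells_set_missing
        # scrambled order (complete cases first) keeps row04: different output
        scrambled = complete_cases(table)
        assert "row04" in scrambled.X.index

    def test_correction_model_fitted_after_filters(self):
        # the mostly-missing column must not reach the correction model
        table = build_table(
            X={
                "A": [5.0, 5.0, 7.0],
                "B": [np.nan, np.nan, 1.0],
            },
            study_id=[1, 1, 1],
            animal_number=[1, 2, 21],
            timepoint_h=[24, 24, 24],
        )
        cc, model, _ = curate(table, max_col_missing=0.5)
        assert list(model.gm.index) == ["A"]


class TestModelSerialisation:
    def test_json_round_trip(self, tmp_path, default_cohort):
        model = fit_median_centring(default_cohort)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = CorrectionModel.from_json(path)
        assert back.mode == model.mode
        pd.testing.assert_series_equal(back.gm, model.gm, check_names=False)
        assert np.allclose(back.sm.to_numpy(), model.sm.to_numpy(), equal_nan=True)
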