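"""Engine contracts: preservation, donors, convergence, determinism, signal."""

import numpy as np
import pandas as pd
import pytest

from imputeval import (
    EngineParams,
    ImputationInput,
    apply_mask,
    initial_impute,
    make_mask,
    merge_imputations,
    micerf_impute,
    missforest_impute,
    nrmse,
)
from imputeval.engines import EngineError


def linear_pair_data(n: int = 200, seed: int = 0) -> pd.DataFrame:
    """y = 2x exactly; a noiseless planted relationship."""
    rng = np.random.default_rng(seed)
    x = rng.lognormal(2.0, 0.4, n)
    return pd.DataFrame({"x": x, "y": 2 * x})


def masked_y(data: pd.DataFrame, frac: float, seed: int):
    rng = np.random.default_rng(seed)
    pattern = pd.DataFrame(False, index=data.index, columns=data.columns)
    rows = rng.choice(len(data), size=int(frac * len(data)), replace=False)
    pattern.iloc[rows, pattern.columns.get_loc("y")] = True
    return data.mask(pattern), pattern


class TestInitialImpute:
    def test_mean_for_continuous(self):
        inp = ImputationInput(pd.DataFrame({"a": [2.0, 4.0, np.nan]}), ["a"])
        assert initial_impute(inp)["a"].iloc[2] == 3.0

    def test_identity_when_complete(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        out = initial_impute(ImputationInput(df, ["a"]))
        pd.testing.assert_frame_equal(out, df)

    def test_mode_for_categorical(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": ["a", "a", None]})
        df["c"] = df["c"].astype(object)
        out = initial_impute(ImputationInput(df, ["a"]))
        assert out["c"].iloc[2] == "a"

    def test_all_missing_column_rejected(self):
        inp = ImputationInput(pd.DataFrame({"a": [np.nan, np.nan]}), ["a"])
        with pytest.raises(EngineError, match="column-all-missing"):
            initial_impute(inp)


class TestMissForest:
    def test_zero_missing_is_identity(self):
        df = linear_pair_data(50)
        out, info = missforest_impute(ImputationInput(df, ["x", "y"]), EngineParams(seed=1))
        pd.testing.assert_frame_equal(out, df)
        assert info.iterations_run == 1
        assert info.stopped_reason == "no-missing"

    def test_observed_cells_bit_identical(self):
        df = linear_pair_data(120)
        masked, pattern = masked_y(df, 0.2, seed=3)
        out, _ = missforest_impute(ImputationInput(masked, ["x", "y"]), EngineParams(seed=1))
        obs = ~pattern.to_numpy()
        assert (out.to_numpy()[obs] == df.to_numpy()[obs]).all()

    def test_recovers_noiseless_linear_signal(self):
        df = linear_pair_data(200, seed=4)
        masked, pattern = masked_y(df, 0.2, seed=5)
        out, _ = missforest_impute(ImputationInput(masked, ["x", "y"]), EngineParams(seed=2))
        truth = df["y"][pattern["y"]]
        imputed = out["y"][pattern["y"]]
        rel_err = np.abs(imputed - truth) / truth
        assert (rel_err < 0.10).mean() >= 0.90

    def test_deterministic(self):
        df = linear_pair_data(80)
        masked, _ = masked_y(df, 0.25, seed=6)
        inp = ImputationInput(masked, ["x", "y"])
        a, ia = missforest_impute(inp, EngineParams(seed=7))
        b, ib = missforest_impute(inp, EngineParams(seed=7))
        assert a.equals(b)
        assert ia.delta_trace == ib.delta_trace

    def test_convergence_trace_sane(self):
        df = linear_pair_data(150, seed=8)
        masked, _ = masked_y(df, 0.3, seed=9)
        _, info = missforest_impute(ImputationInput(masked, ["x", "y"]), EngineParams(seed=3))
        assert len(info.delta_trace) == info.iterations_run
        assert all(np.isfinite(d) and d >= 0 for d in info.delta_trace)
        assert info.stopped_reason in ("criterion-rise", "max-iter")
        if info.stopped_reason == "criterion-rise":
            assert info.delta_trace[-1] >= info.delta_trace[-2]

    def test_factor_cap_enforced(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "a": rng.normal(size=120),
                "big": [f"lvl{i % 60}" for i in range(120)],
            }
        )
        df.loc[df.index[:10], "a"] = np.nan
        with pytest.raises(EngineError, match="factor-cap-exceeded"):
            missforest_impute(ImputationInput(df, ["a"]), EngineParams(seed=0))

    def test_underdetermined_column_rejected(self):
        df = pd.DataFrame({"a": [1.0] + [np.nan] * 9, "b": np.arange(10.0)})
        with pytest.raises(EngineError, match="column-underdetermined"):
            missforest_impute(ImputationInput(df, ["a", "b"]), EngineParams(seed=0))


class TestMicerf:
    def test_imputed_values_are_donors(self):
        df = linear_pair_data(150, seed=10)
        masked, pattern = masked_y(df, 0.3, seed=11)
        chains = micerf_impute(ImputationInput(masked, ["x", "y"]), EngineParams(mice_m=3, seed=4))
        observed_y = set(masked["y"].dropna())
        for chain in chains:
            assert set(chain["y"][pattern["y"]]) <= observed_y

    def test_constant_observed_column(self):
        df = pd.DataFrame({"a": [5.0] * 10 + [np.nan] * 3, "b": np.arange(13.0)})
        chains = micerf_impute(ImputationInput(df, ["a"]), EngineParams(mice_m=2, seed=0))
        for chain in chains:
            assert (chain["a"] == 5.0).all()

    def test_zero_missing_identity(self):
        df = linear_pair_data(40)
        chains = micerf_impute(ImputationInput(df, ["x", "y"]), EngineParams(mice_m=3, seed=0))
        assert len(chains) == 3
        for chain in chains:
            pd.testing.assert_frame_equal(chain, df)

    def test_observed_cells_bit_identical_and_deterministic(self):
        df = linear_pair_data(100, seed=12)
        masked, pattern = masked_y(df, 0.2, seed=13)
        inp = ImputationInput(masked, ["x", "y"])
        a = micerf_impute(inp, EngineParams(mice_m=2, seed=5))
        b = micerf_impute(inp, EngineParams(mice_m=2, seed=5))
        for ca, cb in zip(a, b):
            assert ca.equals(cb)
        obs = ~pattern.to_numpy()
        assert (a[0].to_numpy()[obs] == df.to_numpy()[obs]).all()

    def test_chains_differ(self):
        df = linear_pair_data(100, seed=14)
        masked, pattern = masked_y(df, 0.3, seed=15)
        chains = micerf_impute(ImputationInput(masked, ["x", "y"]), EngineParams(mice_m=2, seed=6))
        assert not chains[0]["y"][pattern["y"]].equals(chains[1]["y"][pattern["y"]])

    def test_high_cardinality_factor_allowed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "a": rng.normal(10, 1, size=120),
                "big": [f"lvl{i % 60}" for i in range(120)],
            }
        )
        df.loc[df.index[:10], "a"] = np.nan
        chains = micerf_impute(ImputationInput(df, ["a"]), EngineParams(mice_m=1, seed=0))
        assert chains[0]["a"].notna().all()


class TestMerge:
    def test_mean_of_continuous(self):
        tables = [pd.DataFrame({"a": [v]}) for v in (2.0, 4.0, 6.0)]
        assert merge_imputations(tables)["a"].iloc[0] == 4.0

    def test_single_table_identity(self):
        t = pd.DataFrame({"a": [1.0, 2.0]})
        pd.testing.assert_frame_equal(merge_imputations([t]), t)

    def test_mode_of_categorical(self):
        tables = [pd.DataFrame({"c": [v]}) for v in ("a", "b", "a")]
        assert merge_imputations(tables)["c"].iloc[0] == "a"

    def test_shape_mismatch_rejected(self):
        with pytest.raises(EngineError, match="merge-mismatch"):
            merge_imputations([pd.DataFrame({"a": [1.0]}), pd.DataFrame({"b": [1.0]})])


class TestSignalExploitation:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_both_engines_beat_mean_imputation(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(3.8, 0.35, 250)
        noise_sd = np.sqrt(1.1**2 * x.var() * (1 / 0.86 - 1))
        df = pd.DataFrame({"ALT": x, "AST": 1.1 * x + 40 + rng.normal(0, noise_sd, 250)})
        mask = make_mask(df, "MCAR", 0.2, seed=seed)
        masked = apply_mask(df, mask)
        inp = ImputationInput(masked, ["ALT", "AST"])
        mf, _ = missforest_impute(inp, EngineParams(seed=seed))
        mice = merge_imputations(micerf_impute(inp, EngineParams(mice_m=3, seed=seed)))
        mean_filled = masked.fillna(masked.mean())
        base = nrmse(df, mean_filled, mask.pattern)
        assert nrmse(df, mf, mask.pattern) < base
        assert nrmse(df, mice, mask.pattern) < base
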