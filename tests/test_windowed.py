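import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pm_gapfill.errors import ContractViolationError, InsufficientDataError, InvalidConfigError
from pm_gapfill.gaps import find_gaps
from pm_gapfill.synthetic import GeneratorConfig, generate_series
from pm_gapfill.windowed import (
    ImputerSpec,
    Scaler,
    WindowedImputer,
    assemble_features,
    build_training_windows,
    fit,
    fuse_bidirectional,
    fusion_weights,
    predict_autoregressive,
    predict_seq2seq,
    scale_fit_transform,
    split_time_based,
)


def univariate_frame(values):
    v = np.asarray(values, dtype=float)
    return pd.DataFrame({"pm25": v}, index=pd.date_range("2024-01-01", periods=len(v), freq="h"))


class TestSpec:
    def test_invalid_strategy(self):
        with pytest.raises(InvalidConfigError):
            ImputerSpec(strategy="magic")

    def test_context_sides(self):
        assert ImputerSpec(strategy="seq2seq", directionality="unidirectional").context_sides == 2
        assert ImputerSpec(strategy="seq2seq", directionality="bidirectional").context_sides == 1
        assert ImputerSpec(strategy="autoregressive", directionality="unidirectional").context_sides == 1


class TestBuildWindows:
    def test_autoregressive_count(self):
        frame = univariate_frame(np.arange(100.0))
        spec = ImputerSpec(strategy="autoregressive", directionality="unidirectional", window=32)
        ws = build_training_windows(frame, spec)
        assert ws.inputs.shape == (68, 32)  # 100 - 32
        assert ws.targets.shape == (68, 1)

    def test_seq2seq_one_sided_count(self):
        frame = univariate_frame(np.arange(100.0))
        spec = ImputerSpec(strategy="seq2seq", directionality="bidirectional", window=32, horizon=12)
        ws = build_training_windows(frame, spec)
        assert ws.inputs.shape == (57, 32)  # 100 - 32 - 12 + 1
        assert ws.targets.shape == (57, 12)

    def test_seq2seq_two_sided_count(self):
        frame = univariate_frame(np.arange(100.0))
        spec = ImputerSpec(strategy="seq2seq", directionality="unidirectional", window=32, horizon=12)
        ws = build_training_windows(frame, spec)
        assert ws.inputs.shape == (25, 64)  # 100 - 64 - 12 + 1

    def test_holes_disqualify_windows(self):
        v = np.arange(200.0)
        v[::33] = np.nan  # a hole every 33rd position
        frame = univariate_frame(v)
        spec = ImputerSpec(strategy="autoregressive", directionality="unidirectional", window=32)
        with pytest.raises(InsufficientDataError):
            build_training_windows(frame, spec)

    def test_examples_are_hole_free(self):
        v = np.arange(300.0)
        v[100:110] = np.nan
        frame = univariate_frame(v)
        spec = ImputerSpec(strategy="seq2seq", directionality="bidirectional", window=16, horizon=4)
        ws = build_training_windows(frame, spec)
        assert np.isfinite(ws.inputs).all() and np.isfinite(ws.targets).all()

    def test_multivariate_flattened_width(self):
        series = generate_series(GeneratorConfig(n_hours=200, seed=0))
        spec = ImputerSpec(
            strategy="seq2seq", directionality="bidirectional", variables="multivariate",
            window=32, horizon=4,
        )
        ws = build_training_windows(series, spec)
        assert ws.inputs.shape[1] == 32 * 5  # 5 features per step


class TestFusion:
    def test_singleton_is_average(self):
        assert fuse_bidirectional([1.0], [0.0])[0] == pytest.approx(0.5)

    def test_declared_weight_formula(self):
        out = fuse_bidirectional([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        np.testing.assert_allclose(out, [0.75, 0.5, 0.25])

    def test_identical_inputs_fixed_point(self):
        v = np.array([3.0, 1.0, 4.0])
        np.testing.assert_allclose(fuse_bidirectional(v, v), v)

    def test_weights_sum_to_one(self):
        for L in (1, 2, 5, 72):
            w = fusion_weights(L)
            np.testing.assert_allclose(w + w[::-1], 1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ContractViolationError):
            fuse_bidirectional([1.0, 2.0], [1.0])

    @given(st.integers(1, 40), st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_output_bounded_by_inputs(self, L, seed):
        rng = np.random.default_rng(seed)
        f, b = rng.normal(size=L), rng.normal(size=L)
        out = fuse_bidirectional(f, b)
        assert np.all(out >= np.minimum(f, b) - 1e-12)
        assert np.all(out <= np.maximum(f, b) + 1e-12)


class TestScaler:
    def test_two_point_standardization(self):
        frame = univariate_frame([0.0, 2.0])
        scaled, _, scaler = scale_fit_transform(frame)
        np.testing.assert_allclose(scaled["pm25"], [-1.0, 1.0])

    def test_inverse_roundtrip(self):
        frame = univariate_frame(np.random.default_rng(0).normal(30, 5, 50))
        scaled, _, scaler = scale_fit_transform(frame)
        back = scaler.inverse_transform_column(scaled["pm25"].to_numpy())
        np.testing.assert_allclose(back, frame["pm25"].to_numpy(), rtol=1e-12)

    def test_constant_feature_guard(self):
        frame = univariate_frame([7.0] * 10)
        scaled, _, _ = scale_fit_transform(frame)
        np.testing.assert_allclose(scaled["pm25"], 0.0)

    def test_frozen_map_applied_elsewhere(self):
        train = univariate_frame([0.0, 2.0])
        other = univariate_frame([4.0])
        _, [scaled_other], _ = scale_fit_transform(train, [other])
        np.testing.assert_allclose(scaled_other["pm25"], [3.0])  # (4-1)/1


class TestSplit:
    def test_basic_split(self):
        frame = univariate_frame(np.arange(10.0))
        train, test = split_time_based(frame)
        assert len(train) == 8 and len(test) == 2

    def test_paper_sized_split(self):
        frame = univariate_frame(np.zeros(5791))
        train, test = split_time_based(frame)
        assert len(train) == 4632 and len(test) == 1159

    def test_chronological_no_shuffle(self):
        frame = univariate_frame(np.arange(10.0))
        train, test = split_time_based(frame)
        assert train.index.max() < test.index.min()


class _LastValueBackend:
    """Fake backend returning the last input column."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        return X[:, -1]


class TestPredict:
    def test_autoregressive_constant_extrapolation(self):
        from pm_gapfill.windowed import FittedModel

        spec = ImputerSpec(strategy="autoregressive", directionality="unidirectional", window=4)
        fitted = FittedModel(spec=spec, models=[_LastValueBackend()], n_inputs=4)
        out = predict_autoregressive(fitted, np.array([1.0, 2.0, 3.0, 9.0]), 5)
        np.testing.assert_allclose(out, 9.0)

    def test_wrong_context_length_raises(self):
        from pm_gapfill.windowed import FittedModel

        spec = ImputerSpec(strategy="autoregressive", directionality="unidirectional", window=4)
        fitted = FittedModel(spec=spec, models=[_LastValueBackend()], n_inputs=4)
        with pytest.raises(ContractViolationError):
            predict_autoregressive(fitted, np.array([1.0, 2.0]), 3)

    def test_seq2seq_horizon_and_mismatch(self):
        frame = univariate_frame(np.sin(np.arange(300.0) / 5) + 10)
        spec = ImputerSpec(strategy="seq2seq", directionality="bidirectional", window=16, horizon=12)
        fitted = fit(spec, build_training_windows(frame, spec), seed=0)
        out = predict_seq2seq(fitted, np.zeros(16), 12)
        assert out.shape == (12,)
        with pytest.raises(ContractViolationError):
            predict_seq2seq(fitted, np.zeros(15), 12)

    def test_constant_training_series_predicts_constant(self):
        frame = univariate_frame(np.full(120, 5.0))
        spec = ImputerSpec(strategy="seq2seq", directionality="bidirectional", window=8, horizon=4)
        fitted = fit(spec, build_training_windows(frame, spec), seed=0)
        out = predict_seq2seq(fitted, np.full(8, 5.0), 4)
        np.testing.assert_allclose(out, 5.0, atol=1e-9)

    def test_horizon_one_equals_autoregressive_one_step(self):
        frame = univariate_frame(np.sin(np.arange(400.0) / 7) * 3 + 20)
        ar_spec = ImputerSpec(strategy="autoregressive", directionality="unidirectional", window=16)
        s2s_spec = ImputerSpec(strategy="seq2seq", directionality="bidirectional", window=16, horizon=1)
        ar_ws = build_training_windows(frame, ar_spec)
        s2s_ws = build_training_windows(frame, s2s_spec)
        np.testing.assert_allclose(ar_ws.inputs, s2s_ws.inputs)
        np.testing.assert_allclose(ar_ws.targets, s2s_ws.targets)
        ar_fit = fit(ar_spec, ar_ws, seed=5)
        s2s_fit = fit(s2s_spec, s2s_ws, seed=5)
        ctx = frame["pm25"].to_numpy()[-16:]
        a = predict_autoregressive(ar_fit, ctx, 1)
        b = predict_seq2seq(s2s_fit, ctx, 1)
        np.testing.assert_allclose(a, b)


class TestAssembleFeatures:
    def test_univariate_single_column(self):
        series = generate_series(GeneratorConfig(n_hours=100, seed=0))
        out = assemble_features(series, np.arange(32), "univariate")
        assert out.shape == (32, 1)

    def test_multivariate_five_columns(self):
        series = generate_series(GeneratorConfig(n_hours=100, seed=0))
        out = assemble_features(series, np.arange(32), "multivariate")
        assert out.shape == (32, 5)

    def test_temporal_encoding(self):
        idx = pd.date_range("2024-12-15 13:00", periods=1, freq="h")
        frame = pd.DataFrame(
            {"pm25": [1.0], "T": [0.0], "U": [0.0], "hour": idx.hour, "season": [1]}, index=idx
        )
        row = assemble_features(frame, np.array([0]), "multivariate")
        assert row[0, 3] == 13  # hour
        assert row[0, 4] == 1  # winter


class TestWindowedImputer:
    @pytest.fixture(scope="class")
    def series(self):
        return generate_series(GeneratorConfig(n_hours=1500, seed=8))

    def test_end_to_end_bidirectional(self, series):
        spec = ImputerSpec(strategy="seq2seq", directionality="bidirectional", window=16, horizon=6)
        imputer = WindowedImputer(spec, seed=0).fit(series.iloc[:1200])
        holed = series.copy()
        holed.iloc[1300:1306, 0] = np.nan
        gap = find_gaps(holed)[0]
        out = imputer.impute(holed, gap)
        assert out.shape == (6,)
        assert np.all(np.isfinite(out))
        truth = series["pm25"].iloc[1300:1306].to_numpy()
        # sanity: beats the trivial all-zeros prediction
        assert np.abs(out - truth).mean() < np.abs(truth).mean()

    def test_fusion_beats_single_direction(self):
        # two fused directional models use strictly more information than
        # either direction alone; check the forward-only comparison
        from pm_gapfill.synthetic import GapPattern, GeneratorConfig, generate_series, inject_missingness
        from pm_gapfill.windowed import fuse_bidirectional, predict_seq2seq
        from pm_gapfill.evaluation import metric_mae
        from pm_gapfill.gaps import GapSpec

        bi_maes, fwd_maes = [], []
        for seed in range(5):
            series = generate_series(GeneratorConfig(n_hours=3000, seed=seed))
            train = series.iloc[:2400]
            spec = ImputerSpec(strategy="seq2seq", directionality="bidirectional", horizon=12)
            imputer = WindowedImputer(spec, seed=7).fit(train)
            test = series.iloc[2400:]
            _, gaps = inject_missingness(test, GapPattern(12), seed=100 + seed)
            holed = series.copy()
            col = holed.columns.get_loc("pm25")
            for g in gaps:
                holed.iloc[2400 + g.start : 2400 + g.stop, col] = np.nan
            scaled = imputer.scaler.transform(holed)
            truths, fused, forward = [], [], []
            for g in gaps:
                full = GapSpec(g.start + 2400, g.length, g.left_context, g.right_context, g.truth)
                left = imputer._context_block(scaled, full, "left")
                f = predict_seq2seq(imputer.forward_, left.ravel(), full.length)
                right = imputer._context_block(scaled, full, "right")[::-1]
                b = predict_seq2seq(imputer.backward_, right.ravel(), full.length)[::-1]
                truths.append(g.truth)
                fused.append(imputer.scaler.inverse_transform_column(fuse_bidirectional(f, b)))
                forward.append(imputer.scaler.inverse_transform_column(f))
            y = np.concatenate(truths)
            bi_maes.append(metric_mae(y, np.concatenate(fused)))
            fwd_maes.append(metric_mae(y, np.concatenate(forward)))
        assert np.median(bi_maes) <= np.median(fwd_maes)

    def test_deterministic_fit_and_predict(self, series):
        spec = ImputerSpec(strategy="seq2seq", directionality="unidirectional", window=16, horizon=6)
        holed = series.copy()
        holed.iloc[1300:1306, 0] = np.nan
        gap = find_gaps(holed)[0]
        a = WindowedImputer(spec, seed=3).fit(series.iloc[:1200]).impute(holed, gap)
        b = WindowedImputer(spec, seed=3).fit(series.iloc[:1200]).impute(holed, gap)
        np.testing.assert_allclose(a, b)
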