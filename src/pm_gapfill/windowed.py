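"""Fixed-context supervised imputers.

Two framings over pluggable regression backends (tree ensembles by default):

* autoregressive — one-step-ahead models applied recursively across the gap;
* sequence-to-sequence — the whole gap predicted in one pass from fixed
  context windows (left only, left+right concatenated, or two directional
  models fused by distance weights).

Models train and predict on the standardized scale; predictions are mapped
back to ug/m3 before scoring.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor

from pm_gapfill.errors import (
    ContractViolationError,
    InsufficientDataError,
    InvalidConfigError,
    MethodInapplicableError,
)
from pm_gapfill.gaps import GapSpec

#: Feature set of the multivariate fixed-context models (5 features).
MULTIVARIATE_FEATURES = ("pm25", "T", "U", "hour", "season")


def derive_seed(master_seed: int, *tags: object) -> int:
    """Stable per-(model, run) seed derived from a master seed by hashing."""
    digest = hashlib.sha256(repr((master_seed,) + tags).encode()).digest()
    return int.from_bytes(digest[:4], "little")


def make_backend(name: str, n_estimators: int, seed: int):
    """Instantiate a regression backend by family name."""
    if name == "rf":
        return RandomForestRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    if name == "gbrt":
        return HistGradientBoostingRegressor(max_iter=n_estimators, random_state=seed)
    raise InvalidConfigError(f"unknown backend {name!r}; registered: rf, gbrt")


@dataclass(frozen=True)
class ImputerSpec:
    """Declarative description of one fixed-context method."""

    strategy: str = "seq2seq"  # autoregressive | seq2seq
    directionality: str = "bidirectional"  # unidirectional | bidirectional
    variables: str = "univariate"  # univariate | multivariate
    backend: str = "gbrt"
    window: int = 32
    horizon: int = 1
    n_estimators: int = 50
    feature_names: tuple[str, ...] = MULTIVARIATE_FEATURES

    def __post_init__(self) -> None:
        if self.strategy not in ("autoregressive", "seq2seq"):
            raise InvalidConfigError(f"unknown strategy {self.strategy!r}")
        if self.directionality not in ("unidirectional", "bidirectional"):
            raise InvalidConfigError(f"unknown directionality {self.directionality!r}")
        if self.variables not in ("univariate", "multivariate"):
            raise InvalidConfigError(f"unknown variables {self.variables!r}")
        if self.window < 1 or self.horizon < 1:
            raise InvalidConfigError("window and horizon must be >= 1")

    @property
    def features(self) -> tuple[str, ...]:
        return ("pm25",) if self.variables == "univariate" else self.feature_names

    @property
    def context_sides(self) -> int:
        """Input sides per model: unidirectional seq2seq concatenates the
        left and right windows ("32/32"); every other variant is one-sided."""
        return 2 if (self.strategy, self.directionality) == ("seq2seq", "unidirectional") else 1


@dataclass
class SupervisedWindowSet:
    """Flattened training examples (time-major, then feature)."""

    inputs: np.ndarray  # [n_examples, window * sides * n_features]
    targets: np.ndarray  # [n_examples, horizon] or [n_examples, 1]


def split_time_based(series: pd.DataFrame, train_fraction: float = 0.8) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chronological prefix/suffix split, no shuffling."""
    if not 0.0 < train_fraction <= 1.0:
        raise InvalidConfigError("train_fraction must lie in (0, 1]")
    n_train = int(np.floor(train_fraction * len(series)))
    return series.iloc[:n_train], series.iloc[n_train:]


class Scaler:
    """Per-column standardization fitted on the training split only.

    Zero-variance columns get a unit scale floor so constants map to 0.
    The inverse transform is exact to round-off.
    """

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.scale_: pd.Series | None = None

    def fit(self, train: pd.DataFrame) -> "Scaler":
        numeric = train.select_dtypes(include=[np.number])
        self.mean_ = numeric.mean()
        scale = numeric.std(ddof=0)
        scale[~(scale > 1e-12)] = 1.0
        self.scale_ = scale
        return self

    def _check(self) -> None:
        if self.mean_ is None:
            raise ContractViolationError("scaler not fitted")

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        self._check()
        out = frame.copy()
        cols = [c for c in self.mean_.index if c in out.columns]
        out[cols] = (out[cols] - self.mean_[cols]) / self.scale_[cols]
        return out

    def inverse_transform_column(self, values: np.ndarray, column: str = "pm25") -> np.ndarray:
        self._check()
        return np.asarray(values, dtype=float) * self.scale_[column] + self.mean_[column]


def scale_fit_transform(
    train: pd.DataFrame, apply_to: Sequence[pd.DataFrame] = ()
) -> tuple[pd.DataFrame, list[pd.DataFrame], Scaler]:
    """Fit a scaler on ``train`` and apply the same affine map elsewhere."""
    scaler = Scaler().fit(train)
    return scaler.transform(train), [scaler.transform(f) for f in apply_to], scaler


def _observed_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal fully observed stretches."""
    ok = ~mask
    if not ok.any():
        return []
    boundaries = np.flatnonzero(np.diff(ok.astype(np.int8)))
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [len(mask)]))
    return [(s, e) for s, e in zip(starts, ends) if ok[s]]


def build_training_windows(series: pd.DataFrame, spec: ImputerSpec) -> SupervisedWindowSet:
    """Slide windows over fully observed stretches of the (scaled) series.

    Autoregressive examples pair a ``window``-long input block with the next
    value; seq2seq examples pair the context block(s) with the next
    ``horizon`` values (two-sided variants flank the target on both sides).
    Examples slide by one step and never contain missing values.
    """
    features = list(spec.features)
    data = series[features].to_numpy(dtype=float)
    missing = np.isnan(data).any(axis=1)

    w, h = spec.window, spec.horizon
    target_col = features.index("pm25")
    span = w + 1 if spec.strategy == "autoregressive" else spec.context_sides * w + h

    inputs, targets = [], []
    for s, e in _observed_runs(missing):
        for i in range(s, e - span + 1):
            if spec.strategy == "autoregressive":
                inputs.append(data[i : i + w].ravel())
                targets.append(data[i + w, target_col : target_col + 1])
            elif spec.context_sides == 1:
                inputs.append(data[i : i + w].ravel())
                targets.append(data[i + w : i + w + h, target_col])
            else:
                left = data[i : i + w]
                right = data[i + w + h : i + 2 * w + h]
                inputs.append(np.concatenate((left.ravel(), right.ravel())))
                targets.append(data[i + w : i + w + h, target_col])
    if not inputs:
        raise InsufficientDataError(
            f"no fully observed stretch of length {span} for window={w}, horizon={h}"
        )
    return SupervisedWindowSet(np.asarray(inputs), np.asarray(targets))


@dataclass
class FittedModel:
    """Per-horizon-step backends over a shared flattened input."""

    spec: ImputerSpec
    models: list  # one regressor per target column
    n_inputs: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_inputs:
            raise ContractViolationError(f"expected {self.n_inputs} input columns, got {x.shape[1]}")
        return np.column_stack([m.predict(x) for m in self.models])


def fit(spec: ImputerSpec, windows: SupervisedWindowSet, seed: int = 0) -> FittedModel:
    """Fit one independent regressor per target column (multi-output as a
    bank of single-output backends over the shared input)."""
    n_targets = windows.targets.shape[1]
    models = []
    for j in range(n_targets):
        backend = make_backend(spec.backend, spec.n_estimators, derive_seed(seed, spec.backend, j))
        backend.fit(windows.inputs, windows.targets[:, j])
        models.append(backend)
    return FittedModel(spec=spec, models=models, n_inputs=windows.inputs.shape[1])


def predict_autoregressive(
    fitted: FittedModel,
    left_context: np.ndarray,
    length: int,
    future_covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Recursive one-step forecasting across the gap.

    ``left_context`` is a [window, n_features] block (or [window] univariate).
    In multivariate mode ``future_covariates`` supplies the non-target feature
    rows for each gap position.
    """
    spec = fitted.spec
    context = np.atleast_2d(np.asarray(left_context, dtype=float))
    if context.shape == (1, spec.window):
        context = context.T
    if context.shape != (spec.window, len(spec.features)):
        raise ContractViolationError(
            f"left context must be [window={spec.window} x {len(spec.features)} features], got {context.shape}"
        )
    target_col = list(spec.features).index("pm25")
    rolling = context.copy()
    out = np.empty(length)
    for i in range(length):
        out[i] = fitted.predict(rolling.ravel()[None, :])[0, 0]
        new_row = np.zeros(rolling.shape[1])
        if rolling.shape[1] > 1:
            if future_covariates is None:
                raise ContractViolationError("multivariate autoregression needs future covariates")
            new_row = np.asarray(future_covariates[i], dtype=float).copy()
        new_row[target_col] = out[i]
        rolling = np.vstack((rolling[1:], new_row))
    return out


def predict_seq2seq(fitted: FittedModel, context: np.ndarray, length: int) -> np.ndarray:
    """Single forward pass; returns the first ``length`` of the horizon."""
    if length > len(fitted.models):
        raise ContractViolationError(
            f"requested {length} values from a horizon-{len(fitted.models)} model"
        )
    flat = np.asarray(context, dtype=float).ravel()
    if flat.shape[0] != fitted.n_inputs:
        raise ContractViolationError(f"expected {fitted.n_inputs} context values, got {flat.shape[0]}")
    return fitted.predict(flat[None, :])[0, :length]


def fusion_weights(length: int) -> np.ndarray:
    """Forward-model weights w_i = (L + 1 - i) / (L + 1), i = 1..L."""
    if length < 1:
        raise ContractViolationError("fusion length must be >= 1")
    i = np.arange(1, length + 1, dtype=float)
    return (length + 1 - i) / (length + 1)


def fuse_bidirectional(forward: np.ndarray, backward: np.ndarray) -> np.ndarray:
    """Distance-weighted fusion of forward and backward predictions.

    ``backward`` must already be in gap time order.  The forward weight
    decays linearly from near 1 at the gap's left edge to near 0 at its
    right edge; weights sum pairwise to 1.
    """
    forward = np.asarray(forward, dtype=float)
    backward = np.asarray(backward, dtype=float)
    if forward.shape != backward.shape or forward.ndim != 1:
        raise ContractViolationError("forward/backward predictions must be 1-D and equally long")
    w = fusion_weights(len(forward))
    return w * forward + (1.0 - w) * backward


def assemble_features(
    series: pd.DataFrame,
    positions: np.ndarray,
    variables: str = "univariate",
    feature_names: Sequence[str] = MULTIVARIATE_FEATURES,
) -> np.ndarray:
    """Feature matrix at the given positions (rows = positions)."""
    cols = ["pm25"] if variables == "univariate" else list(feature_names)
    return series.iloc[np.asarray(positions)][cols].to_numpy(dtype=float)


class WindowedImputer:
    """Benchmark-facing wrapper: owns its scaler, directional models and the
    context extraction/fusion logic for a fixed gap length (horizon)."""

    def __init__(self, spec: ImputerSpec, seed: int = 0, name: str | None = None) -> None:
        self.spec = spec
        self.seed = seed
        self.name = name or "-".join(
            (spec.backend, spec.strategy, spec.directionality[:3], spec.variables[:5])
        )
        self.scaler: Scaler | None = None
        self.forward_: FittedModel | None = None
        self.backward_: FittedModel | None = None

    def fit(self, train: pd.DataFrame) -> "WindowedImputer":
        self.scaler = Scaler().fit(train[list(self.spec.features)])
        scaled = self.scaler.transform(train)
        self.forward_ = fit(self.spec, build_training_windows(scaled, self.spec), self.seed)
        if self.spec.directionality == "bidirectional":
            reversed_scaled = scaled.iloc[::-1].reset_index(drop=True)
            self.backward_ = fit(
                self.spec, build_training_windows(reversed_scaled, self.spec), derive_seed(self.seed, "bwd")
            )
        return self

    # -- context helpers ------------------------------------------------

    def _context_block(self, scaled: pd.DataFrame, gap: GapSpec, side: str) -> np.ndarray:
        w = self.spec.window
        if side == "left":
            lo, hi = gap.start - w, gap.start
        else:
            lo, hi = gap.stop, gap.stop + w
        if lo < 0 or hi > len(scaled):
            raise MethodInapplicableError(f"gap at {gap.start} lacks a full {side} window of {w}")
        block = assemble_features(scaled, np.arange(lo, hi), self.spec.variables, self.spec.feature_names)
        if np.isnan(block[:, 0]).any():
            raise MethodInapplicableError(f"{side} context of gap at {gap.start} contains missing pm25")
        if np.isnan(block).any():  # covariates assumed near-complete; patch locally
            block = np.where(
                np.isnan(block),
                np.array(pd.DataFrame(block).interpolate(limit_direction="both")),
                block,
            )
        return block

    def impute(self, series: pd.DataFrame, gap: GapSpec) -> np.ndarray:
        if self.scaler is None or self.forward_ is None:
            raise ContractViolationError("imputer not fitted")
        spec = self.spec
        scaled = self.scaler.transform(series)

        if spec.strategy == "autoregressive":
            left = self._context_block(scaled, gap, "left")
            covs = None
            if spec.variables == "multivariate":
                covs = assemble_features(scaled, gap.positions, spec.variables, spec.feature_names)
            pred = predict_autoregressive(self.forward_, left, gap.length, covs)
            if self.backward_ is not None:
                right = self._context_block(scaled, gap, "right")[::-1]
                back = predict_autoregressive(
                    self.backward_, right, gap.length, None if covs is None else covs[::-1]
                )[::-1]
                pred = fuse_bidirectional(pred, back)
        else:
            if gap.length > spec.horizon:
                raise MethodInapplicableError(
                    f"gap of {gap.length} exceeds trained horizon {spec.horizon}"
                )
            if spec.directionality == "unidirectional":
                left = self._context_block(scaled, gap, "left")
                right = self._context_block(scaled, gap, "right")
                context = np.concatenate((left.ravel(), right.ravel()))
                pred = predict_seq2seq(self.forward_, context, gap.length)
            else:
                left = self._context_block(scaled, gap, "left")
                fwd = predict_seq2seq(self.forward_, left.ravel(), gap.length)
                right = self._context_block(scaled, gap, "right")[::-1]
                back = predict_seq2seq(self.backward_, right.ravel(), gap.length)[::-1]
                pred = fuse_bidirectional(fwd, back)

        return self.scaler.inverse_transform_column(pred, "pm25")
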