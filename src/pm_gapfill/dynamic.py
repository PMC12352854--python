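"""Dynamic adaptive-context imputer: one model for gaps of any length.

Key mechanics: context windows sized as a function of gap length (3x rule
with a cap), position-aware zero padding so observed values always sit
adjacent to the gap, explicit gap metadata features, a single multi-output
fit across all trained gap lengths, and chunked filling for gaps longer
than the trained maximum.  Padding zeros live on the standardized scale,
where zero is the training mean (i.e. uninformative).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from pm_gapfill.errors import ContractViolationError, InsufficientDataError, InvalidConfigError
from pm_gapfill.gaps import GapSpec, find_gaps
from pm_gapfill.synthetic import season_of_month
from pm_gapfill.windowed import Scaler, derive_seed, make_backend

logger = logging.getLogger(__name__)

#: Time-varying covariates of the multivariate dynamic model; hour and
#: season of the gap start ride along as scalar metadata.
DYNAMIC_FEATURES = ("Ff", "DD", "T", "U", "hour", "season")


@dataclass(frozen=True)
class DynamicConfig:
    c_max: int = 32
    context_factor: int = 3
    short_gap_cutoff: int = 10
    max_trained_gap: int = 72
    trained_gap_lengths: tuple[int, ...] = (5, 12, 24, 48, 72)
    variables: str = "univariate"  # univariate | multivariate
    feature_names: tuple[str, ...] = DYNAMIC_FEATURES
    n_estimators: int = 50
    backend: str = "gbrt"
    max_examples_per_length: int = 400

    def __post_init__(self) -> None:
        if self.c_max < 1 or self.context_factor < 1 or self.short_gap_cutoff < 1:
            raise InvalidConfigError("c_max, context_factor and short_gap_cutoff must be >= 1")
        if any(l < 1 or l > self.max_trained_gap for l in self.trained_gap_lengths):
            raise InvalidConfigError("trained_gap_lengths must lie in [1, max_trained_gap]")
        if self.variables not in ("univariate", "multivariate"):
            raise InvalidConfigError(f"unknown variables {self.variables!r}")

    @property
    def covariates(self) -> tuple[str, ...]:
        """Time-varying covariate blocks (hour/season enter as scalars)."""
        if self.variables == "univariate":
            return ()
        return tuple(f for f in self.feature_names if f not in ("hour", "season"))


def dynamic_context_size(gap_length: int, config: DynamicConfig | None = None) -> int:
    """Context per side: 3 x gap length for short gaps, capped at c_max."""
    config = config or DynamicConfig()
    if gap_length < 1:
        raise ContractViolationError("gap_length must be >= 1")
    if gap_length <= config.short_gap_cutoff:
        return min(config.context_factor * gap_length, config.c_max)
    return config.c_max


def pad_context(left: np.ndarray, right: np.ndarray, c_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad context blocks away from the gap.

    Left context pads on the far-left (most recent values stay adjacent to
    the gap); right context pads on the far-right (earliest post-gap values
    stay adjacent).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if len(left) > c_max or len(right) > c_max:
        raise ContractViolationError("context longer than c_max")
    left_block = np.concatenate((np.zeros(c_max - len(left)), left))
    right_block = np.concatenate((right, np.zeros(c_max - len(right))))
    return left_block, right_block


@dataclass
class PaddedExample:
    """One training example of the unified multi-length training set."""

    left_block: np.ndarray  # [c_max]
    right_block: np.ndarray  # [c_max]
    metadata: tuple[float, ...]  # (gap_length, effective_context_size, ...)
    covariate_blocks: np.ndarray  # [n_cov * max_trained_gap], empty if univariate
    target: np.ndarray  # [max_trained_gap], NaN beyond the gap
    mask: np.ndarray  # [max_trained_gap] bool

    def input_vector(self) -> np.ndarray:
        return np.concatenate(
            (self.left_block, self.right_block, np.asarray(self.metadata, dtype=float), self.covariate_blocks)
        )


def _covariate_blocks(scaled: pd.DataFrame, start: int, length: int, config: DynamicConfig) -> np.ndarray:
    """Scaled covariate values across the gap, zero-padded to max_trained_gap."""
    blocks = []
    for name in config.covariates:
        col = scaled[name].to_numpy(dtype=float)[start : start + length]
        col = np.nan_to_num(col, nan=0.0)  # near-complete; absent -> uninformative
        blocks.append(np.concatenate((col, np.zeros(config.max_trained_gap - length))))
    return np.concatenate(blocks) if blocks else np.zeros(0)


def _scalar_metadata(scaled: pd.DataFrame, start: int, length: int, ctx: int, config: DynamicConfig) -> tuple:
    meta: list[float] = [float(length), float(ctx)]
    if config.variables == "multivariate":
        ts = scaled.index[start]
        meta += [float(ts.hour), float(season_of_month(ts.month))]
    return tuple(meta)


def _make_example(
    scaled: pd.DataFrame,
    values: np.ndarray,
    start: int,
    length: int,
    config: DynamicConfig,
    left_avail: int | None = None,
    right_avail: int | None = None,
) -> PaddedExample:
    ctx = dynamic_context_size(length, config)
    k = ctx if left_avail is None else min(left_avail, ctx)
    m = ctx if right_avail is None else min(right_avail, ctx)
    left = values[start - k : start] if k > 0 else np.zeros(0)
    right = values[start + length : start + length + m] if m > 0 else np.zeros(0)
    left_block, right_block = pad_context(left, right, config.c_max)
    target = np.full(config.max_trained_gap, np.nan)
    mask = np.zeros(config.max_trained_gap, dtype=bool)
    target[:length] = values[start : start + length]
    mask[:length] = True
    return PaddedExample(
        left_block=left_block,
        right_block=right_block,
        metadata=_scalar_metadata(scaled, start, length, ctx, config),
        covariate_blocks=_covariate_blocks(scaled, start, length, config),
        target=target,
        mask=mask,
    )


def build_dynamic_training_set(
    scaled: pd.DataFrame, config: DynamicConfig, seed: int = 0
) -> list[PaddedExample]:
    """Carve simulated gaps of every trained length from observed stretches.

    Candidate gap positions require full dynamic context on both sides; they
    are subsampled deterministically to at most ``max_examples_per_length``
    per gap length.  A length too long for the available stretches is
    skipped with a warning.
    """
    values = scaled["pm25"].to_numpy(dtype=float)
    missing = np.isnan(values)
    rng = np.random.default_rng(derive_seed(seed, "dynamic-train"))
    examples: list[PaddedExample] = []

    # maximal observed runs
    runs = []
    i = 0
    n = len(values)
    while i < n:
        if missing[i]:
            i += 1
            continue
        j = i
        while j < n and not missing[j]:
            j += 1
        runs.append((i, j))
        i = j

    for length in config.trained_gap_lengths:
        ctx = dynamic_context_size(length, config)
        candidates = [
            s + ctx + off
            for s, e in runs
            for off in range(max(0, (e - s) - 2 * ctx - length + 1))
        ]
        if not candidates:
            logger.warning("no observed stretch can host a %d-hour training gap; skipped", length)
            continue
        if len(candidates) > config.max_examples_per_length:
            picked = rng.choice(len(candidates), size=config.max_examples_per_length, replace=False)
            chosen = sorted(candidates[p] for p in picked)
        else:
            chosen = candidates
        for start in chosen:
            examples.append(_make_example(scaled, values, start, length, config))
    if not examples:
        raise InsufficientDataError("training split too fragmented for any trained gap length")
    return examples


@dataclass
class FittedDynamicImputer:
    """One multi-output regressor bank over [left | right | metadata | covariates]."""

    config: DynamicConfig
    scaler: Scaler | None
    models: list  # per output position: fitted backend or ("const", value)
    n_inputs: int

    def predict_outputs(self, x: np.ndarray, n_outputs: int) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_inputs:
            raise ContractViolationError(f"expected {self.n_inputs} input columns, got {x.shape[1]}")
        out = np.empty(n_outputs)
        for j in range(n_outputs):
            model = self.models[j]
            out[j] = model[1] if isinstance(model, tuple) else model.predict(x)[0]
        return out


def fit_dynamic(
    config: DynamicConfig,
    examples: Sequence[PaddedExample],
    seed: int = 0,
    scaler: Scaler | None = None,
) -> FittedDynamicImputer:
    """Fit the multi-output regressor bank on padded examples.

    Each of the ``max_trained_gap`` output positions gets its own backend,
    trained only on examples whose mask covers that position; a position
    with no covering examples degenerates to the training-target mean.
    """
    X = np.vstack([ex.input_vector() for ex in examples])
    targets = np.vstack([ex.target for ex in examples])
    masks = np.vstack([ex.mask for ex in examples])
    overall_mean = float(np.nanmean(targets))

    models = []
    for j in range(config.max_trained_gap):
        rows = masks[:, j]
        if not rows.any():
            logger.warning("output position %d has no covering examples; degenerates to mean", j)
            models.append(("const", overall_mean))
            continue
        backend = make_backend(config.backend, config.n_estimators, derive_seed(seed, "dyn", j))
        backend.fit(X[rows], targets[rows, j])
        models.append(backend)
    return FittedDynamicImputer(config=config, scaler=scaler, models=models, n_inputs=X.shape[1])


class DynamicImputer:
    """Benchmark-facing dynamic imputer (fit once, fill gaps of any length)."""

    def __init__(self, config: DynamicConfig | None = None, seed: int = 0, name: str | None = None) -> None:
        self.config = config or DynamicConfig()
        self.seed = seed
        self.name = name or f"dynamic-{self.config.variables[:5]}"
        self.fitted_: FittedDynamicImputer | None = None

    def fit(self, train: pd.DataFrame) -> "DynamicImputer":
        config = self.config
        columns = ["pm25", *config.covariates]
        self.scaler_ = Scaler().fit(train[columns])
        scaled = self.scaler_.transform(train)
        examples = build_dynamic_training_set(scaled, config, self.seed)
        self.fitted_ = fit_dynamic(config, examples, self.seed, self.scaler_)
        return self

    # -- prediction ------------------------------------------------------

    def _predict_scaled(self, scaled: pd.DataFrame, values: np.ndarray, gap: GapSpec) -> np.ndarray:
        """Direct prediction (scaled space) for gap.length <= max_trained_gap."""
        config = self.config
        if gap.length > config.max_trained_gap:
            raise ContractViolationError(
                f"gap of {gap.length} exceeds max trained length {config.max_trained_gap}; chunk it"
            )
        example = _make_example(
            scaled, values, gap.start, gap.length, config,
            left_avail=gap.left_context, right_avail=gap.right_context,
        )
        x = example.input_vector()
        return self.fitted_.predict_outputs(x, gap.length)

    def predict_gap(self, series: pd.DataFrame, gap: GapSpec) -> np.ndarray:
        """Fill one gap (<= max trained length) on the raw scale."""
        if self.fitted_ is None:
            raise ContractViolationError("imputer not fitted")
        scaled = self.scaler_.transform(series)
        values = scaled["pm25"].to_numpy(dtype=float)
        pred = self._predict_scaled(scaled, values, gap)
        return self.scaler_.inverse_transform_column(pred, "pm25")

    def fill_long_gap(self, series: pd.DataFrame, gap: GapSpec) -> np.ndarray:
        """Chunked fill: full max-length chunks left-to-right plus a remainder.

        Each chunk after the first uses the just-predicted values as its left
        context, preserving continuity at chunk seams.
        """
        if self.fitted_ is None:
            raise ContractViolationError("imputer not fitted")
        config = self.config
        if gap.length <= config.max_trained_gap:
            raise ContractViolationError("fill_long_gap is for gaps longer than max_trained_gap")
        chunks = chunk_lengths(gap.length, config.max_trained_gap)
        scaled = self.scaler_.transform(series)
        values = scaled["pm25"].to_numpy(dtype=float)
        out = np.empty(gap.length)
        offset = 0
        for chunk in chunks:
            start = gap.start + offset
            left_ctx = _contiguous_left(values, start)
            right_ctx = _contiguous_right(values, start + chunk)
            sub = GapSpec(start=start, length=chunk, left_context=left_ctx, right_context=right_ctx)
            pred = self._predict_scaled(scaled, values, sub)
            values[start : start + chunk] = pred  # chain predictions as context
            out[offset : offset + chunk] = pred
            offset += chunk
        return self.scaler_.inverse_transform_column(out, "pm25")

    def impute(self, series: pd.DataFrame, gap: GapSpec) -> np.ndarray:
        if gap.length <= self.config.max_trained_gap:
            return self.predict_gap(series, gap)
        return self.fill_long_gap(series, gap)

    def fill_all(self, series: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
        """Fill every gap; negative predictions are clipped to zero.

        Returns the filled series and a per-gap report (start timestamp,
        length, method path, chunk sizes, context used, clip count).
        """
        out = series.copy()
        report: list[dict] = []
        for gap in find_gaps(out):
            chunked = gap.length > self.config.max_trained_gap
            pred = self.impute(out, gap)
            n_clipped = int((pred < 0).sum())
            pred = np.clip(pred, 0.0, None)
            out.iloc[gap.start : gap.stop, out.columns.get_loc("pm25")] = pred
            report.append(
                {
                    "start_timestamp": str(series.index[gap.start]),
                    "length": gap.length,
                    "method": "chunked" if chunked else "direct",
                    "chunks": chunk_lengths(gap.length, self.config.max_trained_gap) if chunked else [gap.length],
                    "left_context": gap.left_context,
                    "right_context": gap.right_context,
                    "n_clipped": n_clipped,
                }
            )
        return out, report


def chunk_lengths(gap_length: int, max_chunk: int) -> list[int]:
    """Segment a long gap into full chunks plus a trailing remainder."""
    n_full, remainder = divmod(int(gap_length), int(max_chunk))
    return [int(max_chunk)] * n_full + ([int(remainder)] if remainder else [])


def _contiguous_left(values: np.ndarray, position: int) -> int:
    """Observed run length immediately left of ``position``."""
    k = 0
    while position - 1 - k >= 0 and not np.isnan(values[position - 1 - k]):
        k += 1
    return k


def _contiguous_right(values: np.ndarray, position: int) -> int:
    k = 0
    while position + k < len(values) and not np.isnan(values[position + k]):
        k += 1
    return k
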