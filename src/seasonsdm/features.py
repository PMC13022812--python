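"""Model input assembly: annual (M0), seasonal (M1) and chained (M2) features.

With V climate variables the three families see V, 3V and 3V + 2 inputs: the
time-static family averages the 12 monthly climatologies per variable; the
seasonal families concatenate the season's 3 monthly values (month-major,
winter ordered Dec, Jan, Feb); the chained family appends the previous
season's predicted occurrence probability and a binary chain-start flag.
Climate features are z-scored on the training split; the two chain inputs
pass through untouched so prev_prob keeps its probability semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_climate import ClimateStack, cell_of
from .occurrences import SEASON_MONTHS

PREV_PROB = ("prev_prob",)
START_FLAG = ("start_flag",)
#: Initial chain state: previous-season probability 0.5, start flag 0.
CHAIN_INIT: tuple[float, int] = (0.5, 0)


class MaskedCellError(ValueError):
    """A sample fell on a cell without valid climate data."""


@dataclass
class FeatureVector:
    values: np.ndarray
    schema: tuple


@dataclass
class ChainState:
    """Chain inputs for the concatenated family at one step."""

    prev_prob: float = 0.5
    start_flag: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= float(np.min(self.prev_prob)) <= float(np.max(self.prev_prob)) <= 1.0:
            raise ValueError("prev_prob must lie in [0, 1]")
        if self.start_flag not in (0, 1):
            raise ValueError("start_flag must be 0 or 1")


def static_schema(variables) -> tuple:
    return tuple((v, "annual") for v in variables)


def seasonal_schema(variables, season: str) -> tuple:
    return tuple((v, m) for m in SEASON_MONTHS[season] for v in variables)


def chained_schema(variables, season: str) -> tuple:
    return seasonal_schema(variables, season) + (PREV_PROB, START_FLAG)


def _check_valid(stack: ClimateStack, rows, cols) -> None:
    ok = stack.valid[rows, cols]
    if not np.all(ok):
        raise MaskedCellError("sample falls on a cell without valid climate data")


def static_matrix(stack: ClimateStack, rows, cols) -> np.ndarray:
    """(n, V) matrix of per-variable annual means (unweighted over 12 months)."""
    _check_valid(stack, rows, cols)
    return stack.values[:, :, rows, cols].mean(axis=1).T


def seasonal_matrix(stack: ClimateStack, season: str, rows, cols) -> np.ndarray:
    """(n, 3V) matrix: season's monthly values, month-major, variables within."""
    _check_valid(stack, rows, cols)
    blocks = [stack.values[:, m - 1, rows, cols].T for m in SEASON_MONTHS[season]]
    return np.concatenate(blocks, axis=1)


def chained_matrix(stack: ClimateStack, season: str, rows, cols,
                   prev_prob, start_flag) -> np.ndarray:
    """(n, 3V + 2) matrix: seasonal block plus [prev_prob, start_flag]."""
    X = seasonal_matrix(stack, season, rows, cols)
    n = X.shape[0]
    prev = np.broadcast_to(np.asarray(prev_prob, dtype=float), (n,))
    if prev.min() < 0 or prev.max() > 1:
        raise ValueError("prev_prob must lie in [0, 1]")
    d = np.broadcast_to(np.asarray(start_flag, dtype=float), (n,))
    return np.column_stack([X, prev, d])


def build_static_features(point, stack: ClimateStack) -> FeatureVector:
    row, col = cell_of(point[0], point[1], stack.grid)
    vals = static_matrix(stack, np.array([row]), np.array([col]))[0]
    return FeatureVector(vals, static_schema(stack.variables))


def build_seasonal_features(point, stack: ClimateStack, season: str) -> FeatureVector:
    row, col = cell_of(point[0], point[1], stack.grid)
    vals = seasonal_matrix(stack, season, np.array([row]), np.array([col]))[0]
    return FeatureVector(vals, seasonal_schema(stack.variables, season))


def build_chained_features(point, stack: ClimateStack, season: str,
                           chain: ChainState) -> FeatureVector:
    row, col = cell_of(point[0], point[1], stack.grid)
    vals = chained_matrix(stack, season, np.array([row]), np.array([col]),
                          chain.prev_prob, chain.start_flag)[0]
    return FeatureVector(vals, chained_schema(stack.variables, season))


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on training samples.

    Chain inputs (prev_prob, start_flag) are passed through unchanged; constant
    climate features get their standard deviation clamped to 1 so they map to 0.
    """

    mean_: np.ndarray
    sd_: np.ndarray
    passthrough: np.ndarray = field(default=None)

    @classmethod
    def fit(cls, X: np.ndarray, schema: tuple | None = None) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training samples to fit a standardizer")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd <= 0, 1.0, sd)
        if schema is not None:
            passthrough = np.array([name in (PREV_PROB, START_FLAG) for name in schema])
        else:
            passthrough = np.zeros(X.shape[1], dtype=bool)
        mean = np.where(passthrough, 0.0, mean)
        sd = np.where(passthrough, 1.0, sd)
        return cls(mean_=mean, sd_=sd, passthrough=passthrough)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd_ + self.mean_

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "sd": self.sd_.tolist(),
                "passthrough": self.passthrough.astype(int).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(np.asarray(d["mean"]), np.asarray(d["sd"]),
                   np.asarray(d["passthrough"], dtype=bool))


def fit_standardizer(train_features: np.ndarray, schema: tuple | None = None) -> Standardizer:
    return Standardizer.fit(train_features, schema)


def apply_standardizer(standardizer: Standardizer, features: np.ndarray) -> np.ndarray:
    return standardizer.transform(features)
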