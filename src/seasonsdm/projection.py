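"""Niche maps, change statistics, range shifts and scenario agreement.

A trained family plus a climate stack yields per-season probability rasters;
binarizing at the validation TSS thresholds gives seasonal niche maps, their
union the any-season niche and their intersection the year-round niche (the
model-output year-round layer uses no adjacency pruning — that rule cleans
observations, not predictions).  Comparing two periods gives lost/gained cell
sets and percentages relative to the present niche, and order statistics of
suitable-cell coordinates quantify latitudinal/longitudinal shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_climate import ClimateStack, GridSpec, cell_center
from .models import SeasonalModelSet, predict_cells
from .occurrences import SEASONS


@dataclass
class NicheMaps:
    """Probability and binary rasters for one period/scenario."""

    grid: GridSpec
    probability: dict[str, np.ndarray]          # season -> (rows, cols) float
    binary: dict[str, np.ndarray]               # season -> bool raster
    any_season: np.ndarray = None               # union of seasonal binaries
    year_round: np.ndarray = None               # intersection of seasonal binaries
    period_label: str = ""
    scenario_label: str = ""

    def __post_init__(self) -> None:
        if self.any_season is None:
            self.any_season = np.logical_or.reduce([self.binary[s] for s in SEASONS])
        if self.year_round is None:
            self.year_round = np.logical_and.reduce([self.binary[s] for s in SEASONS])

    def layer(self, name: str) -> np.ndarray:
        if name in SEASONS:
            return self.binary[name]
        if name == "any_season":
            return self.any_season
        if name == "year_round":
            return self.year_round
        raise KeyError(name)


LAYERS: tuple[str, ...] = SEASONS + ("any_season", "year_round")


def project_niche(model_set: SeasonalModelSet, stack: ClimateStack,
                  thresholds: dict[str, float] | None = None) -> NicheMaps:
    """Predict per-cell seasonal probabilities and binarize at th_s.

    Thresholds default to the ones stored on the model set (estimated on the
    present-day validation split and reused unchanged for past and future
    stacks).  Cells with invalid climate get probability NaN and binary False.
    """
    thresholds = thresholds or model_set.thresholds
    if not thresholds:
        raise RuntimeError("no thresholds available; run evaluation first")
    rows, cols = np.nonzero(stack.valid)
    probs = predict_cells(model_set, stack, rows, cols)
    probability, binary = {}, {}
    for s in SEASONS:
        pr = np.full(stack.grid.shape, np.nan)
        pr[rows, cols] = probs[s]
        probability[s] = pr
        binary[s] = np.zeros(stack.grid.shape, dtype=bool)
        binary[s][rows, cols] = probs[s] >= thresholds[s]
    return NicheMaps(stack.grid, probability, binary,
                     period_label=stack.period_label,
                     scenario_label=stack.scenario_label)


@dataclass
class ChangeResult:
    lost: np.ndarray        # bool raster: suitable now, not in future
    gained: np.ndarray      # bool raster: suitable in future, not now
    lost_pct: float | None  # 100 * |lost| / |present|; None if present empty
    gained_pct: float | None


def change_map(present: NicheMaps, future: NicheMaps, layer: str) -> ChangeResult:
    """Lost/gained cells between two periods for one niche layer.

    Percentages are relative to the present niche size (gained_pct may exceed
    100); with an empty present niche they are flagged undefined (None).
    """
    a = present.layer(layer)
    b = future.layer(layer)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    lost = a & ~b
    gained = b & ~a
    n_present = int(a.sum())
    if n_present == 0:
        return ChangeResult(lost, gained, None, None)
    return ChangeResult(lost, gained,
                        100.0 * lost.sum() / n_present,
                        100.0 * gained.sum() / n_present)


def shift_stats(binary_map: np.ndarray, grid: GridSpec) -> dict[str, dict[str, float]]:
    """Median and 5th/95th percentiles of suitable-cell center coordinates.

    One value per suitable cell, unweighted; percentiles use the linear
    interpolation convention.
    """
    rows, cols = np.nonzero(binary_map)
    if len(rows) == 0:
        raise ValueError("empty niche map: no suitable cells")
    lat, lon = cell_center(rows, cols, grid)
    out = {}
    for name, vals in (("latitude", lat), ("longitude", lon)):
        out[name] = {
            "p5": float(np.percentile(vals, 5)),
            "median": float(np.percentile(vals, 50)),
            "p95": float(np.percentile(vals, 95)),
        }
    return out


def scenario_agreement(change_sets: list[np.ndarray]) -> np.ndarray:
    """Per-cell count of scenarios flagging the cell (lost or gained).

    Full agreement = count equal to the number of scenarios.
    """
    if len(change_sets) < 2:
        raise ValueError("need at least 2 scenarios")
    shape = change_sets[0].shape
    for c in change_sets[1:]:
        if c.shape != shape:
            raise ValueError("scenario rasters on different grids")
    return np.sum([c.astype(int) for c in change_sets], axis=0)


@dataclass
class ShiftReport:
    """Change statistics between a present and one future period."""

    scenario_label: str
    layers: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def compute(cls, present: NicheMaps, future: NicheMaps,
                scenario_label: str = "") -> "ShiftReport":
        report = cls(scenario_label=scenario_label or future.scenario_label)
        for layer in LAYERS:
            entry: dict = {}
            change = change_map(present, future, layer)
            entry["lost_pct"] = change.lost_pct
            entry["gained_pct"] = change.gained_pct
            for period, maps in (("present", present), ("future", future)):
                try:
                    entry[period] = shift_stats(maps.layer(layer), maps.grid)
                except ValueError:
                    entry[period] = None
            if entry["present"] and entry["future"]:
                entry["shift"] = {
                    coord: {q: entry["future"][coord][q] - entry["present"][coord][q]
                            for q in ("p5", "median", "p95")}
                    for coord in ("latitude", "longitude")
                }
            else:
                entry["shift"] = None
            report.layers[layer] = entry
        return report

    def to_dict(self) -> dict:
        return {"scenario": self.scenario_label, "layers": self.layers}
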