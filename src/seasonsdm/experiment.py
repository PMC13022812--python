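"""End-to-end experiment glue: dataset assembly, training and evaluation.

This module wires the pieces together the way a full study run does: simulate
(or load) climate and occurrences, build the background contrast set inside
the buffered presence hull, split presences and background 80/10/10, assemble
and standardize the family's features, train, pick TSS thresholds on the
validation split and report test metrics.  All randomness flows from a single
master seed through named substreams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as F
from .background import BackgroundSet, presence_hull_buffer, sample_background
from .evaluation import EvalReport, evaluate_seasonal
from .grid_climate import ClimateStack, GridSpec, cell_of
from .models import (ChainedSeasonData, SeasonalModelSet, TrainConfig,
                     predict_cells, train_concatenated, train_seasonal_independent,
                     train_static)
from .occurrences import SEASONS, assign_season, split_records
from .synthetic import (SYNTH_VARIABLES, SyntheticTruth, default_truth,
                        simulate_climate, simulate_occurrences)

#: Default 40x40 half-degree synthetic study region.
DEFAULT_GRID = GridSpec(lat_min=20.0, lat_max=40.0, lon_min=-110.0, lon_max=-90.0,
                        cell_size=0.5)


def substream(seed: int, name: str) -> int:
    """Derive a named 31-bit integer sub-seed from the master seed."""
    tag = zlib.crc32(name.encode()) % (2 ** 31)
    h = np.random.SeedSequence([int(seed), tag])
    return int(h.generate_state(1)[0] % (2 ** 31))


@dataclass
class Dataset:
    """One synthetic (or loaded) study dataset shared by all model families."""

    stack: ClimateStack
    records: pd.DataFrame            # presence records with lat/lon/month/season
    background: BackgroundSet
    truth: SyntheticTruth | None = None
    true_q: dict | None = None
    seed: int = 0


def make_dataset(
    seed: int = 0,
    lam: float = 2.0,
    n_presence: int = 2000,
    n_background: int = 2000,
    grid: GridSpec = DEFAULT_GRID,
    variables=SYNTH_VARIABLES,
    buffer_km: float = 100.0,
    noise_amplitude: float = 6.0,
    truth: SyntheticTruth | None = None,
) -> Dataset:
    """Simulate climate + occurrences and sample the background set.

    Background points are shared across the four seasons (the same points are
    featurized with each season's climate and labelled absent in every
    season); points on invalid climate cells are rejected and resampled.
    A custom ``truth`` (e.g. :func:`seasonsdm.synthetic.band_truth`) replaces
    the default patchy-niche parameters; its seed is re-derived from ``seed``.
    """
    stack = simulate_climate(grid, variables, seed=substream(seed, "climate"),
                             noise_amplitude=noise_amplitude)
    if truth is None:
        truth = default_truth(variables, lam=lam, n=n_presence,
                              seed=substream(seed, "occurrences"))
    else:
        truth.seed = substream(seed, "occurrences")
        truth.n = n_presence
    records, true_q = simulate_occurrences(stack, truth)
    region = presence_hull_buffer(records[["lat", "lon"]].to_numpy(), buffer_km)

    def valid_fn(lat, lon):
        inside = (lat >= grid.lat_min) & (lat <= grid.lat_max) & \
                 (lon >= grid.lon_min) & (lon <= grid.lon_max)
        ok = np.zeros(len(lat), dtype=bool)
        if inside.any():
            r, c = cell_of(lat[inside], lon[inside], grid)
            ok[inside] = stack.valid[r, c]
        return ok

    background = sample_background(region, n=n_background,
                                   seed=substream(seed, "background"),
                                   valid_fn=valid_fn)
    return Dataset(stack=stack, records=records, background=background,
                   truth=truth, true_q=true_q, seed=seed)


@dataclass
class SampleSets:
    """Per-split cell indices and labels for one model family's samples."""

    # split -> season -> dict(rows, cols, y)
    per_season: dict[str, dict[str, dict]] = field(default_factory=dict)


def _season_of(records: pd.DataFrame) -> np.ndarray:
    if "season" in records:
        return records["season"].to_numpy()
    return np.array([assign_season(int(m)) for m in records["month"]])


def build_samples(dataset: Dataset, seed: int | None = None) -> SampleSets:
    """Split presences and background 80/10/10 and index them per season.

    Every season's sample set is that season's presence records plus the whole
    (shared) background set, each restricted to the relevant split.
    """
    seed = dataset.seed if seed is None else seed
    grid = dataset.stack.grid
    rec = dataset.records
    prow, pcol = cell_of(rec["lat"].to_numpy(), rec["lon"].to_numpy(), grid)
    season = _season_of(rec)
    bg = dataset.background.points
    brow, bcol = cell_of(bg[:, 0], bg[:, 1], grid)

    p_split = split_records(len(rec), seed=substream(seed, "split-presence"))
    b_split = split_records(len(bg), seed=substream(seed, "split-background"))

    sets = SampleSets()
    for part in ("train", "validation", "test"):
        p_idx = p_split.indices(part)
        b_idx = b_split.indices(part)
        sets.per_season[part] = {}
        for s in SEASONS:
            sp = p_idx[season[p_idx] == s]
            rows = np.r_[prow[sp], brow[b_idx]]
            cols = np.r_[pcol[sp], bcol[b_idx]]
            y = np.r_[np.ones(len(sp)), np.zeros(len(b_idx))]
            sets.per_season[part][s] = {"rows": rows, "cols": cols, "y": y}
    return sets


@dataclass
class ExperimentResult:
    family: str
    model_set: SeasonalModelSet
    report: EvalReport
    dataset: Dataset
    samples: SampleSets


def _train_m0(dataset: Dataset, samples: SampleSets, cfg: TrainConfig) -> SeasonalModelSet:
    stack = dataset.stack

    def xy(part):
        rows = np.concatenate([samples.per_season[part][s]["rows"] for s in SEASONS])
        cols = np.concatenate([samples.per_season[part][s]["cols"] for s in SEASONS])
        y = np.concatenate([samples.per_season[part][s]["y"] for s in SEASONS])
        return F.static_matrix(stack, rows, cols), y

    X_tr, y_tr = xy("train")
    std = F.Standardizer.fit(X_tr)
    X_val, y_val = xy("validation")
    model_set = train_static(std.transform(X_tr), y_tr, std.transform(X_val), y_val, cfg)
    model_set.standardizers = {"static": std}
    return model_set


def _train_m1(dataset: Dataset, samples: SampleSets, cfg: TrainConfig) -> SeasonalModelSet:
    stack = dataset.stack
    stds, train, val = {}, {}, {}
    for s in SEASONS:
        tr = samples.per_season["train"][s]
        X_tr = F.seasonal_matrix(stack, s, tr["rows"], tr["cols"])
        stds[s] = F.Standardizer.fit(X_tr)
        va = samples.per_season["validation"][s]
        X_va = F.seasonal_matrix(stack, s, va["rows"], va["cols"])
        train[s] = (stds[s].transform(X_tr), tr["y"])
        val[s] = (stds[s].transform(X_va), va["y"])
    model_set = train_seasonal_independent(train, val, cfg)
    model_set.standardizers = stds
    return model_set


def _chained_data(stack: ClimateStack, part: dict, stds: dict) -> ChainedSeasonData:
    y = {s: part[s]["y"] for s in SEASONS}
    Z = {s: {t: stds[t].transform(
            F.seasonal_matrix(stack, t, part[s]["rows"], part[s]["cols"]))
            for t in SEASONS}
         for s in SEASONS}
    return ChainedSeasonData(y=y, Z=Z)


def _train_m2(dataset: Dataset, samples: SampleSets, cfg: TrainConfig) -> SeasonalModelSet:
    stack = dataset.stack
    stds = {}
    for s in SEASONS:
        tr = samples.per_season["train"][s]
        stds[s] = F.Standardizer.fit(F.seasonal_matrix(stack, s, tr["rows"], tr["cols"]))
    train = _chained_data(stack, samples.per_season["train"], stds)
    val = _chained_data(stack, samples.per_season["validation"], stds)
    model_set = train_concatenated(train, val, cfg)
    model_set.standardizers = stds
    return model_set


_TRAINERS = {"M0": _train_m0, "M1": _train_m1, "M2": _train_m2}


def train_family(dataset: Dataset, family: str, cfg: TrainConfig | None = None,
                 samples: SampleSets | None = None) -> tuple[SeasonalModelSet, SampleSets]:
    family = family.upper()
    if family not in _TRAINERS:
        raise ValueError(f"unknown family {family!r}; expected M0, M1 or M2")
    if samples is None:
        samples = build_samples(dataset)
    if cfg is None:
        cfg = TrainConfig(seed=substream(dataset.seed, "train"))
    model_set = _TRAINERS[family](dataset, samples, cfg)
    return model_set, samples


def _scores(model_set: SeasonalModelSet, dataset: Dataset, samples: SampleSets,
            part: str) -> tuple[dict, dict]:
    scores, labels = {}, {}
    for s in SEASONS:
        cell = samples.per_season[part][s]
        p = predict_cells(model_set, dataset.stack, cell["rows"], cell["cols"])
        scores[s] = p[s]
        labels[s] = cell["y"]
    return scores, labels


def run_experiment(dataset: Dataset, family: str = "M2",
                   cfg: TrainConfig | None = None) -> ExperimentResult:
    """Train one family on a dataset and evaluate with the full protocol.

    TSS thresholds come from the validation split and are stored on the model
    set (they are reused unchanged for past/future projections); metrics are
    computed on the held-out test split.
    """
    model_set, samples = train_family(dataset, family, cfg)
    val_scores, val_labels = _scores(model_set, dataset, samples, "validation")
    test_scores, test_labels = _scores(model_set, dataset, samples, "test")
    report = evaluate_seasonal(val_scores, val_labels, test_scores, test_labels,
                               family=model_set.family)
    model_set.thresholds = report.thresholds
    return ExperimentResult(family=model_set.family, model_set=model_set,
                            report=report, dataset=dataset, samples=samples)
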