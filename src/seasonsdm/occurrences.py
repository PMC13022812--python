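"""Occurrence ingestion, season binning, data splits and the year-round niche.

Seasons follow boreal-hemisphere labelling: Mar-May spring, Jun-Aug summer,
Sep-Nov fall, Dec-Feb winter.  Winter spans the calendar-year boundary;
December keeps its own year (period climatologies make the year irrelevant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid_climate import GridError, GridSpec, cell_of

#: Season cycle order used everywhere (chaining, reporting).
SEASONS: tuple[str, ...] = ("spring", "summer", "fall", "winter")

_MONTH_TO_SEASON = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
    12: "winter", 1: "winter", 2: "winter",
}

#: Calendar months of each season, in within-season order (winter = Dec, Jan, Feb).
SEASON_MONTHS: dict[str, tuple[int, int, int]] = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "fall": (9, 10, 11),
    "winter": (12, 1, 2),
}

_COLUMN_ALIASES = {
    "lat": ("lat", "latitude", "decimallatitude", "decimalLatitude"),
    "lon": ("lon", "longitude", "decimallongitude", "decimalLongitude"),
    "year": ("year",),
    "month": ("month",),
}


def assign_season(month: int) -> str:
    """Season label for a calendar month (1..12)."""
    month = int(month)
    if month not in _MONTH_TO_SEASON:
        raise ValueError(f"month must be in 1..12, got {month}")
    return _MONTH_TO_SEASON[month]


def next_season(season: str) -> str:
    return SEASONS[(SEASONS.index(season) + 1) % 4]


def previous_season(season: str) -> str:
    return SEASONS[(SEASONS.index(season) - 1) % 4]


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read an occurrence CSV, accepting Darwin-Core column aliases.

    Returns a DataFrame with columns lat, lon, year, month (month is nullable
    Int64: season-free archives simply omit or blank the column).
    """
    df = pd.read_csv(path)
    cols = {}
    lower = {c.lower(): c for c in df.columns}
    for target, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias.lower() in lower:
                cols[target] = lower[alias.lower()]
                break
    missing = {"lat", "lon"} - set(cols)
    if missing:
        raise ValueError(f"occurrence file lacks required columns {sorted(missing)}")
    out = pd.DataFrame({t: df[c] for t, c in cols.items()})
    if "month" in out:
        out["month"] = out["month"].astype("Int64")
        bad = out["month"].dropna()
        if len(bad) and ((bad < 1) | (bad > 12)).any():
            raise ValueError("month values outside 1..12")
    else:
        out["month"] = pd.Series([pd.NA] * len(out), dtype="Int64")
    if "year" not in out:
        out["year"] = pd.Series([pd.NA] * len(out), dtype="Int64")
    return out


@dataclass
class SplitAssignment:
    """Train/validation/test membership for each record index."""

    labels: np.ndarray  # array of "train" | "validation" | "test"
    seed: int

    def indices(self, part: str) -> np.ndarray:
        return np.flatnonzero(self.labels == part)


def split_records(
    n_or_records,
    quotas: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Random train/validation/test split with exact largest-remainder sizes.

    Partition sizes are ``floor(n * quota)`` plus one extra for the largest
    fractional remainders (ties broken in train/validation/test order), so a
    1000-record input under the default quotas yields exactly 800/100/100.
    Membership is a seeded permutation: record order does not bias assignment.
    """
    n = n_or_records if isinstance(n_or_records, (int, np.integer)) else len(n_or_records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    if not np.isclose(sum(quotas), 1.0):
        raise ValueError(f"quotas must sum to 1, got {quotas}")
    raw = np.array([n * q for q in quotas])
    counts = np.floor(raw).astype(int)
    remainder = int(n - counts.sum())
    order = np.argsort(-(raw - counts), kind="stable")
    for k in range(remainder):
        counts[order[k]] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    parts = ("train", "validation", "test")
    start = 0
    for part, c in zip(parts, counts):
        labels[perm[start:start + c]] = part
        start += c
    return SplitAssignment(labels=labels, seed=seed)


@dataclass
class PresenceRaster:
    """Per-season presence cell sets plus per-record cell indices."""

    season_cells: dict[str, set[tuple[int, int]]]
    any_cells: set[tuple[int, int]] = field(default_factory=set)
    record_cells: list[tuple[int, int] | None] = field(default_factory=list)
    rejected: list[int] = field(default_factory=list)


def rasterize_presences(records: pd.DataFrame, grid: GridSpec) -> PresenceRaster:
    """Map presence records onto grid cells, per season and overall.

    Exact duplicate records (same lat, lon, year, month) are deduplicated
    before cell sets are formed.  Off-grid records are collected into
    ``rejected`` (indices into the input), never raised.
    """
    season_cells: dict[str, set] = {s: set() for s in SEASONS}
    any_cells: set = set()
    record_cells: list = []
    rejected: list[int] = []
    seen: set = set()
    for i, row in enumerate(records.itertuples(index=False)):
        key = (row.lat, row.lon, getattr(row, "year", None), getattr(row, "month", None))
        try:
            cell = cell_of(float(row.lat), float(row.lon), grid)
        except GridError:
            rejected.append(i)
            record_cells.append(None)
            continue
        record_cells.append(cell)
        if key in seen:
            continue
        seen.add(key)
        any_cells.add(cell)
        month = getattr(row, "month", None)
        if month is not None and not pd.isna(month):
            season_cells[assign_season(int(month))].add(cell)
    return PresenceRaster(season_cells, any_cells, record_cells, rejected)


def year_round_niche(
    season_cells: dict[str, set[tuple[int, int]]],
    grid: GridSpec | None = None,
    adjacency: str = "queen",
) -> set[tuple[int, int]]:
    """Cells occupied in all four seasons, pruned of isolated singletons.

    Step 1: candidates = intersection of the four seasonal presence sets.
    Step 2: keep a candidate only if at least one adjacent cell (8-neighbour
    queen by default, 4-neighbour rook optional) is also a candidate.  The
    pruning removes isolated records such as museum or greenhouse specimens.
    One pass only (not iterated to a fixed point).
    """
    candidates = set.intersection(*(set(season_cells[s]) for s in SEASONS)) if season_cells else set()
    if adjacency == "queen":
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    elif adjacency == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError(f"unknown adjacency {adjacency!r}")
    return {
        c for c in candidates
        if any((c[0] + dr, c[1] + dc) in candidates for dr, dc in offsets)
    }
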