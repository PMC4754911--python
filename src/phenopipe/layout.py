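"""Platform geometry, genotype maps, camera visit order and measurement schedules.

The imaging platform grows plants on a rectangular grid of *tiles* (camera
fields of view), each tile holding a small block of plants (3 x 4 by
default).  The default configuration -- 120 tiles of 12 plants -- gives the
1440-position platform used throughout the rest of the package.  Plants sit
on two irrigation basins; positions carry both platform-level coordinates
(``x``: row, ``y``: column, 0-based) and within-tile coordinates
(``x_within``, ``y_within``) so that downstream mixed models can estimate
spatial design effects at both scales.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "PlantPosition",
    "PlatformLayout",
    "GenotypeEntry",
    "GenotypeMap",
    "MeasurementSchedule",
    "VisitOrder",
    "build_layout",
    "load_genotype_map",
    "visit_order",
    "daily_event_count",
    "scans_per_day",
    "default_schedule",
]


@dataclass(frozen=True)
class PlantPosition:
    """One plant position on the platform.

    ``x``/``y`` are platform-level row/column; ``x_within``/``y_within``
    index the plant inside its tile.  All coordinates are 0-based and
    row-major.
    """

    index: int
    tile: int
    x: int
    y: int
    x_within: int
    y_within: int
    basin: int


@dataclass(frozen=True)
class PlatformLayout:
    """Geometry of the growth platform.

    Parameters
    ----------
    tile_grid
        (rows, cols) of tiles on the platform.
    tile_shape
        (rows, cols) of plants inside one tile; 3 x 4 by default.
    n_basins
        Number of irrigation basins; tiles are split into contiguous
        row-blocks, one per basin.
    plant_pitch_mm
        Centre-to-centre plant distance in millimetres.
    """

    tile_grid: tuple[int, int]
    tile_shape: tuple[int, int] = (3, 4)
    n_basins: int = 2
    plant_pitch_mm: float = 60.0

    def __post_init__(self) -> None:
        for name in ("tile_grid", "tile_shape"):
            r, c = getattr(self, name)
            if r < 1 or c < 1:
                raise ValueError(f"{name} dimensions must be >= 1, got {(r, c)}")
        if self.n_basins < 1:
            raise ValueError("n_basins must be >= 1")

    @property
    def n_tiles(self) -> int:
        return self.tile_grid[0] * self.tile_grid[1]

    @property
    def plants_per_tile(self) -> int:
        return self.tile_shape[0] * self.tile_shape[1]

    @property
    def n_plants(self) -> int:
        return self.n_tiles * self.plants_per_tile

    def tile_row_col(self, tile: int) -> tuple[int, int]:
        if not 0 <= tile < self.n_tiles:
            raise IndexError(f"tile {tile} outside 0..{self.n_tiles - 1}")
        return divmod(tile, self.tile_grid[1])

    def basin_of_tile(self, tile: int) -> int:
        """Basin index for a tile: contiguous row-blocks of tiles."""
        trow, _ = self.tile_row_col(tile)
        rows_per_basin = max(1, -(-self.tile_grid[0] // self.n_basins))
        return min(trow // rows_per_basin, self.n_basins - 1)

    def positions(self) -> list[PlantPosition]:
        """Enumerate every plant position, row-major by tile then plant."""
        out: list[PlantPosition] = []
        idx = 0
        tr_n, tc_n = self.tile_shape
        for tile in range(self.n_tiles):
            trow, tcol = self.tile_row_col(tile)
            basin = self.basin_of_tile(tile)
            for xw in range(tr_n):
                for yw in range(tc_n):
                    out.append(
                        PlantPosition(
                            index=idx,
                            tile=tile,
                            x=trow * tr_n + xw,
                            y=tcol * tc_n + yw,
                            x_within=xw,
                            y_within=yw,
                            basin=basin,
                        )
                    )
                    idx += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        """Positions as a DataFrame (one row per plant)."""
        return pd.DataFrame([vars(p) for p in self.positions()])


def _default_tile_grid(n_tiles: int) -> tuple[int, int]:
    """Near-square factorisation, rows <= cols; 120 -> (10, 12)."""
    best = (1, n_tiles)
    for r in range(1, int(n_tiles**0.5) + 1):
        if n_tiles % r == 0:
            best = (r, n_tiles // r)
    return best


def build_layout(
    n_tiles: int = 120,
    tile_shape: tuple[int, int] = (3, 4),
    tile_grid: tuple[int, int] | None = None,
    n_basins: int = 2,
    plant_pitch_mm: float = 60.0,
) -> PlatformLayout:
    """Construct a :class:`PlatformLayout`.

    ``tile_grid`` defaults to the most nearly square factorisation of
    ``n_tiles`` (10 x 12 for the default 120 tiles).
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    if tile_shape[0] < 1 or tile_shape[1] < 1:
        raise ValueError("tile_shape dimensions must be >= 1")
    if tile_grid is None:
        tile_grid = _default_tile_grid(n_tiles)
    if tile_grid[0] * tile_grid[1] != n_tiles:
        raise ValueError(f"tile_grid {tile_grid} does not hold {n_tiles} tiles")
    return PlatformLayout(
        tile_grid=tile_grid,
        tile_shape=tile_shape,
        n_basins=n_basins,
        plant_pitch_mm=plant_pitch_mm,
    )


# ---------------------------------------------------------------------------
# Genotype map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeEntry:
    genotype: str
    experiment: str
    basin: str
    is_check: bool = False


@dataclass
class GenotypeMap:
    """Mapping from platform position index to genotype/design labels."""

    entries: dict[int, GenotypeEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, position: int) -> GenotypeEntry:
        return self.entries[position]

    def genotypes(self) -> list[str]:
        return sorted({e.genotype for e in self.entries.values()})

    def replicate_counts(self) -> pd.Series:
        """Number of positions per genotype."""
        s = pd.Series([e.genotype for e in self.entries.values()])
        return s.value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": pos,
                "genotype": e.genotype,
                "experiment": e.experiment,
                "basin": e.basin,
                "is_check": e.is_check,
            }
            for pos, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


_GMAP_COLUMNS = ["position", "genotype", "experiment", "basin", "is_check"]


def load_genotype_map(
    source: str | Path | pd.DataFrame,
    layout: PlatformLayout | None = None,
) -> GenotypeMap:
    """Read and validate a genotype map from CSV (or a DataFrame).

    The CSV must carry the header ``position,genotype,experiment,basin,
    is_check``.  Duplicate positions are rejected; when a layout is given,
    positions outside it are rejected too.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in _GMAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype map missing columns: {missing}")
    dupes = df.loc[df["position"].duplicated(), "position"].tolist()
    if dupes:
        raise ValueError(f"duplicate position(s) in genotype map: {sorted(set(dupes))}")
    if (df["genotype"].astype(str).str.len() == 0).any():
        raise ValueError("empty genotype label in genotype map")
    if layout is not None:
        bad = df.loc[
            (df["position"] < 0) | (df["position"] >= layout.n_plants), "position"
        ].tolist()
        if bad:
            raise ValueError(f"position(s) outside layout: {bad}")
    entries = {
        int(r.position): GenotypeEntry(
            genotype=str(r.genotype),
            experiment=str(r.experiment),
            basin=str(r.basin),
            is_check=bool(r.is_check),
        )
        for r in df.itertuples()
    }
    return GenotypeMap(entries)


# ---------------------------------------------------------------------------
# Camera visit order
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VisitOrder:
    """A tile visiting order plus its number of adjacent consecutive pairs."""

    order: tuple[int, ...]
    adjacent_pairs: int


def _adjacent(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1


def _count_adjacent(order: Sequence[int], grid_cols: int) -> int:
    rc = [divmod(t, grid_cols) for t in order]
    return sum(_adjacent(rc[i], rc[i + 1]) for i in range(len(rc) - 1))


def visit_order(layout: PlatformLayout) -> VisitOrder:
    """Tile visiting order that skips immediately neighbouring tiles.

    Consecutive visits to 4-adjacent tiles disturb neighbouring plants with
    the measuring light, so the camera should never image two adjacent
    tiles back to back.  A zero-adjacency permutation is built from the
    checkerboard two-colouring of the tile grid (no two same-colour tiles
    are adjacent), stitching the two colour classes together at a
    non-adjacent junction.  For degenerate grids where no such order exists
    (1x2, 2x1, 2x2) the minimum-adjacency order is found by exhaustive
    search and the residual count is reported.
    """
    rows, cols = layout.tile_grid
    n = rows * cols
    if n == 1:
        return VisitOrder(order=(0,), adjacent_pairs=0)

    black = [t for t in range(n) if sum(divmod(t, cols)) % 2 == 0]
    white = [t for t in range(n) if sum(divmod(t, cols)) % 2 == 1]

    # find a black/white pair that is NOT adjacent to use as the junction
    junction = None
    for b, w in itertools.product(black, white):
        if not _adjacent(divmod(b, cols), divmod(w, cols)):
            junction = (b, w)
            break

    if junction is not None:
        b, w = junction
        order = [t for t in black if t != b] + [b, w] + [t for t in white if t != w]
        count = _count_adjacent(order, cols)
        return VisitOrder(order=tuple(order), adjacent_pairs=count)

    # every cross pair is adjacent: tiny grid, brute-force the minimum
    best_order, best_count = None, n
    for perm in itertools.permutations(range(n)):
        c = _count_adjacent(perm, cols)
        if c < best_count:
            best_order, best_count = perm, c
            if c == 0:
                break
    assert best_order is not None
    return VisitOrder(order=tuple(best_order), adjacent_pairs=best_count)


# ---------------------------------------------------------------------------
# Measurement schedule
# ---------------------------------------------------------------------------

_TASKS = ("phipsii", "nir", "spectral")


@dataclass
class MeasurementSchedule:
    """Daily measurement schedule: (time-of-day in hours, task) events.

    Times are hours after lights-on, in [0, 24); the same schedule repeats
    every day of the experiment.  ``photoperiod_h`` is the number of light
    hours per day, used to annotate events (and downstream statistics) as
    day or night.
    """

    events: list[tuple[float, str]]
    photoperiod_h: float = 10.0

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(t < 0 or t >= 24 for t in times):
            raise ValueError("event times must lie in [0, 24)")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing within a day")
        bad = [task for _, task in self.events if task not in _TASKS]
        if bad:
            raise ValueError(f"unknown task(s) {bad}; expected one of {_TASKS}")
        if not 0 < self.photoperiod_h <= 24:
            raise ValueError("photoperiod_h must lie in (0, 24]")

    def is_day(self, time_h: float) -> bool:
        return (time_h % 24.0) < self.photoperiod_h

    def times(self, task: str | None = None) -> list[float]:
        return [t for t, k in self.events if task is None or k == task]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MeasurementSchedule":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        events = sorted((float(t), str(task)) for task, ts in raw["events"].items() for t in ts)
        return cls(events=events, photoperiod_h=float(raw.get("photoperiod_h", 10.0)))

    def to_yaml(self, path: str | Path) -> None:
        grouped: dict[str, list[float]] = {}
        for t, task in self.events:
            grouped.setdefault(task, []).append(t)
        with open(path, "w") as fh:
            yaml.safe_dump({"photoperiod_h": self.photoperiod_h, "events": grouped}, fh)


def default_schedule(photoperiod_h: float = 10.0) -> MeasurementSchedule:
    """The routine daily protocol.

    Photosystem II efficiency is measured 1, 4 and 7 h into the
    photoperiod; near-infrared plant-size images are taken every 3 h around
    the clock (8 per day), for a total of 11 mask-bearing images per day.
    """
    events = sorted(
        [(float(t), "nir") for t in range(0, 24, 3)]
        + [(1.0, "phipsii"), (4.0, "phipsii"), (7.0, "phipsii")]
    )
    return MeasurementSchedule(events=events, photoperiod_h=photoperiod_h)


def daily_event_count(schedule: MeasurementSchedule, task: str | Iterable[str] | None = None) -> int:
    """Number of scheduled events per day matching a task filter.

    ``task`` may be a single task name, an iterable of names, or None for
    all events.
    """
    if task is None:
        return len(schedule.events)
    wanted = {task} if isinstance(task, str) else set(task)
    return sum(1 for _, k in schedule.events if k in wanted)


def scans_per_day(scan_minutes: float) -> int:
    """How many full-platform scans fit in one day at a given scan time."""
    if scan_minutes <= 0:
        raise ValueError("scan_minutes must be positive")
    return int(24 * 60 // scan_minutes)
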