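"""Tile segmentation: grid reference lines -> per-plant boxes -> threshold
masks -> per-plant trait records.

Each camera image holds one tile of 12 plants (3 x 4).  A user-set grid of
horizontal and vertical reference lines partitions the image into one box
per plant; a greyscale threshold (user-set, or Otsu's method within the
box) separates plant from the black background sheet.  Only pixels inside
the mask contribute to the per-plant trait summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = [
    "GridSpec",
    "Box",
    "PlantMask",
    "PlantRecord",
    "uniform_grid",
    "boxes_from_grid",
    "threshold_mask",
    "summarize_plant",
]


@dataclass(frozen=True)
class Box:
    """Half-open pixel rectangle [r0, r1) x [c0, c1)."""

    r0: int
    r1: int
    c0: int
    c1: int

    def __post_init__(self) -> None:
        if self.r1 <= self.r0 or self.c1 <= self.c0:
            raise ValueError(f"degenerate box {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.r1 - self.r0, self.c1 - self.c0)

    def slice(self) -> tuple[slice, slice]:
        return (slice(self.r0, self.r1), slice(self.c0, self.c1))


@dataclass(frozen=True)
class GridSpec:
    """Reference lines partitioning a tile image into plant boxes.

    Lines include the image edges: a 3 x 4 tile needs 4 horizontal and 5
    vertical lines.  Lines must be strictly increasing.
    """

    horizontal_lines: tuple[int, ...]
    vertical_lines: tuple[int, ...]

    def __post_init__(self) -> None:
        for name, lines in (
            ("horizontal_lines", self.horizontal_lines),
            ("vertical_lines", self.vertical_lines),
        ):
            if len(lines) < 2:
                raise ValueError(f"{name} needs at least 2 lines (the edges)")
            if any(b <= a for a, b in zip(lines, lines[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            if lines[0] < 0:
                raise ValueError(f"{name} contains a negative coordinate")

    @property
    def box_grid(self) -> tuple[int, int]:
        return (len(self.horizontal_lines) - 1, len(self.vertical_lines) - 1)


def uniform_grid(image_shape: tuple[int, int], tile_shape: tuple[int, int] = (3, 4)) -> GridSpec:
    """Evenly spaced grid lines for a given image and plants-per-tile shape."""
    rows, cols = image_shape
    tr, tc = tile_shape
    h = tuple(int(round(i * rows / tr)) for i in range(tr + 1))
    v = tuple(int(round(j * cols / tc)) for j in range(tc + 1))
    return GridSpec(horizontal_lines=h, vertical_lines=v)


def boxes_from_grid(
    grid: GridSpec,
    image_shape: tuple[int, int] | None = None,
    expected_shape: tuple[int, int] | None = None,
) -> list[Box]:
    """Plant boxes from grid lines, row-major, half-open and non-overlapping.

    The boxes tile the grid region exactly once (pixel-count conservation).
    ``expected_shape`` optionally asserts the number of boxes (e.g. (3, 4)).
    """
    if image_shape is not None:
        if grid.horizontal_lines[-1] > image_shape[0] or grid.vertical_lines[-1] > image_shape[1]:
            raise ValueError("grid lines extend beyond the image bounds")
    if expected_shape is not None and grid.box_grid != tuple(expected_shape):
        raise ValueError(
            f"grid defines {grid.box_grid} boxes, expected {tuple(expected_shape)}"
        )
    h, v = grid.horizontal_lines, grid.vertical_lines
    return [
        Box(r0=h[i], r1=h[i + 1], c0=v[j], c1=v[j + 1])
        for i in range(len(h) - 1)
        for j in range(len(v) - 1)
    ]


@dataclass
class PlantMask:
    """Plant/background mask within one plant box."""

    box: Box
    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.box.shape:
            raise ValueError("mask shape must equal the box shape")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def full_frame(self, image_shape: tuple[int, int]) -> np.ndarray:
        """The mask embedded in a full-image boolean array."""
        out = np.zeros(image_shape, dtype=bool)
        out[self.box.slice()] = self.mask
        return out


def threshold_mask(
    image: np.ndarray,
    box: Box,
    threshold: float | str = "auto",
    min_object_px: int | None = None,
) -> PlantMask:
    """Greyscale-threshold plant mask inside one box.

    ``threshold="auto"`` computes Otsu's threshold from the box pixels; a
    numeric value is used as-is (pixels strictly above it are plant).  With
    ``min_object_px`` set, connected foreground specks smaller than that
    many pixels are removed (off by default).
    """
    image = np.asarray(image, dtype=float)
    if box.r1 > image.shape[0] or box.c1 > image.shape[1] or box.r0 < 0 or box.c0 < 0:
        raise ValueError(f"box {box} lies outside the image {image.shape}")
    patch = image[box.slice()]
    if threshold == "auto":
        flat = patch.ravel()
        if np.allclose(flat, flat[0]):
            thr = float(flat[0])  # constant patch: nothing above threshold
        else:
            thr = float(threshold_otsu(patch))
    else:
        thr = float(threshold)
    mask = patch > thr
    if min_object_px is not None and min_object_px > 1 and mask.any():
        mask = remove_small_objects(mask, min_size=min_object_px)
    return PlantMask(box=box, mask=mask, threshold=thr)


@dataclass
class PlantRecord:
    """One plant at one time point for one trait.

    ``mean_value`` is NaN and ``empty`` is True when the mask holds no
    valid pixels.  ``pixel_values`` optionally retains the full per-pixel
    sample for distributional summaries (histograms); the mean alone can
    hide multimodal pixel distributions.
    """

    genotype: str
    tile: int
    x_within: int
    y_within: int
    time_h: float
    trait: str
    mean_value: float
    n_pixels: int
    empty: bool = False
    pixel_values: np.ndarray | None = None
    experiment: str = ""
    basin: str = ""
    x: int = -1
    y: int = -1


def summarize_plant(
    values: np.ndarray,
    mask: PlantMask,
    *,
    genotype: str = "",
    tile: int = -1,
    x_within: int = -1,
    y_within: int = -1,
    time_h: float = float("nan"),
    trait: str = "",
    keep_pixels: bool = False,
    experiment: str = "",
    basin: str = "",
    x: int = -1,
    y: int = -1,
) -> PlantRecord:
    """Summarise a trait image over one plant mask.

    Averages the finite trait values of mask pixels inside the plant box.
    An empty mask yields a flagged record rather than an error, so whole
    tiles can be processed uniformly even when a position is unplanted.
    """
    values = np.asarray(values, dtype=float)
    patch = values[mask.box.slice()]
    sel = mask.mask & np.isfinite(patch)
    pix = patch[sel]
    empty = pix.size == 0
    return PlantRecord(
        genotype=genotype,
        tile=tile,
        x_within=x_within,
        y_within=y_within,
        time_h=time_h,
        trait=trait,
        mean_value=float(pix.mean()) if not empty else float("nan"),
        n_pixels=int(pix.size),
        empty=empty,
        pixel_values=pix.copy() if keep_pixels else None,
        experiment=experiment,
        basin=basin,
        x=x,
        y=y,
    )
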