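"""Spectral reflectance processing: pigment indices, RGB composites and
projected leaf area.

Reflectance is measured in eight narrow bands (480, 532, 550, 570, 660,
700, 750 and 790 nm).  Chlorophyll content is estimated from the red-edge
bands with the Gitelson index

    Chl = (R700^-1 - R790^-1) * R790  =  R790 / R700 - 1,

a linear proxy for leaf chlorophyll.  Near-infrared reflection at 790 nm
images the rosette day and night without perturbing the photoperiod and is
the basis for projected leaf area (PLA), the pixel-count proxy for
above-ground biomass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WAVELENGTHS",
    "ReflectanceCube",
    "PigmentImage",
    "AreaMeasurement",
    "chlorophyll_index",
    "rgb_composite",
    "projected_leaf_area",
    "calibrate_band",
]

WAVELENGTHS = (480, 532, 550, 570, 660, 700, 750, 790)


@dataclass
class ReflectanceCube:
    """Per-wavelength reflectance images, values in [0, 1] after calibration."""

    bands: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("reflectance cube has no bands")
        shapes = set()
        for wl, img in list(self.bands.items()):
            arr = np.asarray(img, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"band {wl} is not a 2D image")
            if np.nanmin(arr) < -1e-9 or np.nanmax(arr) > 1 + 1e-9:
                raise ValueError(f"band {wl} has reflectance outside [0, 1]; calibrate first")
            self.bands[wl] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError("all band images must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def band(self, wavelength: int) -> np.ndarray:
        if wavelength not in self.bands:
            raise KeyError(f"cube is missing the {wavelength} nm band")
        return self.bands[wavelength]


@dataclass
class PigmentImage:
    """Chlorophyll-index image with validity mask (NaN where invalid)."""

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share a shape")
        if self.valid.any() and not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("valid pigment-index pixels must be finite")


@dataclass(frozen=True)
class AreaMeasurement:
    """Projected leaf area: plant pixel count times per-pixel area."""

    pixel_count: int
    pixel_area_mm2: float
    area_mm2: float

    def __post_init__(self) -> None:
        if self.pixel_count < 0 or self.pixel_area_mm2 < 0 or self.area_mm2 < 0:
            raise ValueError("area quantities must be non-negative")


def calibrate_band(counts: np.ndarray, white_reference_mean: float) -> np.ndarray:
    """Linear counts-to-reflectance calibration against a white reference.

    A single per-band gain (the reciprocal of the white-reference mean
    signal) maps raw camera counts to reflectance; results are clipped to
    [0, 1].
    """
    if white_reference_mean <= 0:
        raise ValueError("white reference mean must be positive")
    return np.clip(np.asarray(counts, dtype=float) / white_reference_mean, 0.0, 1.0)


def chlorophyll_index(
    cube: ReflectanceCube,
    mask: np.ndarray | None = None,
    eps: float = 1e-4,
) -> PigmentImage:
    """Gitelson red-edge chlorophyll index per pixel.

    Pixels where either band falls at or below ``eps`` reflectance
    (background, shadow) are flagged invalid rather than allowed to blow up
    through the reciprocal.
    """
    r700 = cube.band(700)
    r790 = cube.band(790)
    if mask is None:
        mask = np.ones(r700.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != r700.shape:
            raise ValueError("mask shape mismatch")
    valid = mask & (r700 > eps) & (r790 > eps)
    values = np.full(r700.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[valid] = (1.0 / r700[valid] - 1.0 / r790[valid]) * r790[valid]
    return PigmentImage(values=values, valid=valid)


def rgb_composite(cube: ReflectanceCube) -> np.ndarray:
    """False-colour RGB from the 660 (red), 570 (green) and 480 (blue) bands.

    All three channels are scaled by a common factor (the maximum signal
    across channels) so relative band intensities -- and hence hue -- are
    preserved; an all-equal cube renders grey.
    """
    channels = [cube.band(wl) for wl in (660, 570, 480)]
    rgb = np.stack(channels, axis=-1)
    peak = rgb.max()
    if peak > 0:
        rgb = rgb / peak
    return np.clip(rgb, 0.0, 1.0)


def projected_leaf_area(
    nir: np.ndarray | None,
    mask: np.ndarray,
    pixel_area_mm2: float,
) -> AreaMeasurement:
    """Projected leaf area from a plant mask.

    ``nir`` is the source image the mask was derived from and is only
    shape-checked; the measurement itself is the mask pixel count times the
    per-pixel ground area, so it is invariant to any intensity rescaling of
    the image.
    """
    if pixel_area_mm2 <= 0:
        raise ValueError("pixel_area_mm2 must be positive")
    mask = np.asarray(mask, dtype=bool)
    if nir is not None and np.asarray(nir).shape != mask.shape:
        raise ValueError("nir image and mask must share a shape")
    count = int(mask.sum())
    return AreaMeasurement(
        pixel_count=count,
        pixel_area_mm2=float(pixel_area_mm2),
        area_mm2=count * float(pixel_area_mm2),
    )
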