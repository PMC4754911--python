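"""Chlorophyll-fluorescence image processing: raw frame stacks to per-pixel
photosystem II operating efficiency.

The measurement protocol images each tile three times per acquisition:

* 24 frames under steady actinic light, averaged into the steady-state
  fluorescence image ``Fs``;
* 6 frames during a saturating light pulse, of which the frame with the
  highest total signal becomes the light-adapted maximum ``Fm'``;
* 24 frames with the measuring LEDs off, averaged into a dark image that
  accounts for background light in the growth chamber.

A broadband fluorescent target imaged at the start of each sequence yields
a multiplicative factor correcting for the different light intensities used
for the ``Fs`` and ``Fm'`` images (after Genty & Meyer).  The operating
efficiency of photosystem II electron transport is then, per pixel,

    phi_PSII = (Fm'_c - Fs_c) / Fm'_c     (also written Fq'/Fm')

with ``Fs_c = (Fs - dark) * factor`` and ``Fm'_c = Fm' - dark``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameStack",
    "EfficiencyImage",
    "TargetCorrection",
    "average_frames",
    "select_fm_prime",
    "compute_target_factor",
    "compute_phipsii",
    "phipsii_histogram",
]

ROLES = ("actinic_Fs", "saturating", "dark", "target")

#: conventional frame counts per acquisition role
EXPECTED_COUNTS = {"actinic_Fs": 24, "saturating": 6, "dark": 24}


@dataclass
class FrameStack:
    """An ordered stack of same-shape greyscale frames with an acquisition role."""

    frames: np.ndarray  # (n_frames, rows, cols)
    role: str
    expected_count: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array or list of 2D frames")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be non-negative")
        if self.expected_count is None:
            self.expected_count = EXPECTED_COUNTS.get(self.role, len(self.frames))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def count_matches(self) -> bool:
        return self.expected_count is None or len(self) == self.expected_count


@dataclass
class TargetCorrection:
    """Multiplicative lamp-intensity correction derived from the fluorescent target."""

    factor: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.factor) or self.factor <= 0:
            raise ValueError(f"correction factor must be finite and > 0, got {self.factor}")


@dataclass
class EfficiencyImage:
    """Per-pixel photosystem II efficiency in [0, 1] with a validity mask.

    Invalid pixels (outside the plant mask, or where the corrected signal
    falls below the noise floor) carry NaN in ``values`` and False in
    ``valid`` -- they are never silently zero.  ``n_clipped`` counts pixels
    whose raw ratio fell outside [0, 1] before clipping.
    """

    values: np.ndarray
    valid: np.ndarray
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share a shape")
        v = self.values[self.valid]
        if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            raise ValueError("valid efficiency values must lie in [0, 1]")


def average_frames(stack: FrameStack) -> np.ndarray:
    """Pixel-wise arithmetic mean of all frames in a stack."""
    if len(stack) == 0:
        raise ValueError("cannot average an empty frame stack")
    return stack.frames.mean(axis=0)


def select_fm_prime(stack: FrameStack, per_pixel_max: bool = False) -> np.ndarray:
    """The maximal-fluorescence image from the saturating-pulse stack.

    By default the single frame with the highest total signal is returned
    whole (ties broken toward the earliest frame); ``per_pixel_max=True``
    instead takes the per-pixel maximum across frames.
    """
    if stack.role != "saturating":
        raise ValueError(f"select_fm_prime expects a saturating stack, got {stack.role!r}")
    if len(stack) == 0:
        raise ValueError("cannot select from an empty frame stack")
    if per_pixel_max:
        return stack.frames.max(axis=0)
    sums = stack.frames.sum(axis=(1, 2))
    return stack.frames[int(np.argmax(sums))].copy()


def compute_target_factor(
    target_under_actinic: np.ndarray,
    target_under_saturating: np.ndarray,
    target_region: np.ndarray,
) -> TargetCorrection:
    """Lamp-intensity correction factor from the fluorescent target.

    The target is imaged under both illumination regimes; the factor is the
    ratio of its mean signal under saturating light to its mean signal
    under actinic light, over the given target region.
    """
    act = np.asarray(target_under_actinic, dtype=float)
    sat = np.asarray(target_under_saturating, dtype=float)
    region = np.asarray(target_region, dtype=bool)
    if act.shape != sat.shape or act.shape != region.shape:
        raise ValueError("target images and region mask must share a shape")
    if not region.any():
        raise ValueError("target region is empty")
    mean_act = act[region].mean()
    if mean_act <= 0:
        raise ValueError("zero mean actinic target signal; cannot form correction factor")
    return TargetCorrection(factor=float(sat[region].mean() / mean_act))


def compute_phipsii(
    fs: np.ndarray,
    fm_prime: np.ndarray,
    dark: np.ndarray,
    correction: TargetCorrection | float = 1.0,
    mask: np.ndarray | None = None,
    noise_floor: float = 5.0,
) -> EfficiencyImage:
    """Per-pixel photosystem II operating efficiency.

    Parameters
    ----------
    fs, fm_prime, dark
        Steady-state, saturating-pulse and dark images (same shape).
    correction
        Lamp-intensity correction applied to the dark-subtracted ``fs``.
    mask
        Optional plant mask; pixels outside it are invalid.
    noise_floor
        Pixels whose dark-subtracted ``Fm'`` is at or below this many
        intensity counts are flagged invalid (the denominator would be
        dominated by noise).
    """
    fs = np.asarray(fs, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if fs.shape != fm_prime.shape or fs.shape != dark.shape:
        raise ValueError("fs, fm_prime and dark must share a shape")
    factor = correction.factor if isinstance(correction, TargetCorrection) else float(correction)
    if mask is None:
        mask = np.ones(fs.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != fs.shape:
            raise ValueError("mask shape mismatch")

    fs_c = (fs - dark) * factor
    fm_c = fm_prime - dark
    valid = mask & (fm_c > noise_floor)

    values = np.full(fs.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (fm_c - fs_c) / fm_c
    n_clipped = int(np.sum(valid & ((raw < 0) | (raw > 1))))
    values[valid] = np.clip(raw[valid], 0.0, 1.0)
    return EfficiencyImage(values=values, valid=valid, n_clipped=n_clipped)


def phipsii_histogram(
    img: EfficiencyImage,
    mask: np.ndarray | None = None,
    bin_width: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-pixel efficiencies over [0, 1].

    Spatially heterogeneous plants (e.g. under nutrient stress) show
    multimodal pixel distributions that a single mean cannot represent;
    the histogram is the standard companion summary.  Returns
    ``(bin_edges, counts)`` with ``counts.sum()`` equal to the number of
    valid masked pixels.
    """
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must lie in (0, 1]")
    sel = img.valid if mask is None else (img.valid & np.asarray(mask, dtype=bool))
    if not sel.any():
        raise ValueError("no valid pixels selected for the histogram")
    n_bins = int(np.ceil(1.0 / bin_width))
    # round edges so that e.g. 0.7 lands in [0.7, 0.8) despite binary floats
    edges = np.minimum(np.round(np.arange(n_bins + 1) * bin_width, 12), 1.0)
    counts, _ = np.histogram(img.values[sel], bins=edges)
    return edges, counts
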