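"""Reading and writing the platform's image formats.

Frame stacks are stored as multi-page TIFF with a YAML sidecar recording
the acquisition role and frame count; efficiency images as 32-bit float
TIFF plus a false-colour PNG; reflectance cubes as one TIFF per band named
by wavelength.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .fluorescence import EfficiencyImage, FrameStack
from .spectral import ReflectanceCube

__all__ = [
    "write_frame_stack",
    "read_frame_stack",
    "write_efficiency_image",
    "read_efficiency_image",
    "write_cube",
    "read_cube",
    "write_tile_images",
    "read_tile_images",
]


def write_frame_stack(directory: str | Path, stack: FrameStack, name: str | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or stack.role
    path = directory / f"{name}.tif"
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    sidecar = {"role": stack.role, "n_frames": len(stack), "expected_count": stack.expected_count}
    with open(directory / f"{name}.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return path


def read_frame_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    sidecar_path = path.with_suffix(".yaml")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            meta = yaml.safe_load(fh)
        return FrameStack(frames, role=meta["role"], expected_count=meta.get("expected_count"))
    raise FileNotFoundError(f"frame stack sidecar not found: {sidecar_path}")


def write_efficiency_image(path_base: str | Path, img: EfficiencyImage) -> tuple[Path, Path]:
    """Float TIFF (NaN outside validity) plus a false-colour PNG preview."""
    import matplotlib

    path_base = Path(path_base)
    path_base.parent.mkdir(parents=True, exist_ok=True)
    tif = path_base.with_suffix(".tif")
    tifffile.imwrite(tif, img.values.astype(np.float32))
    cmap = matplotlib.colormaps["viridis"]
    rgba = cmap(np.nan_to_num(img.values, nan=0.0))
    rgba[~img.valid] = (0, 0, 0, 1)
    png = path_base.with_suffix(".png")
    import imageio.v3 as iio

    iio.imwrite(png, (rgba[..., :3] * 255).astype(np.uint8))
    return tif, png


def read_efficiency_image(path: str | Path) -> EfficiencyImage:
    values = tifffile.imread(path).astype(float)
    return EfficiencyImage(values=values, valid=np.isfinite(values))


def write_cube(directory: str | Path, cube: ReflectanceCube) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for wl, img in cube.bands.items():
        tifffile.imwrite(directory / f"band_{wl}.tif", img.astype(np.float32))


def read_cube(directory: str | Path) -> ReflectanceCube:
    directory = Path(directory)
    bands = {}
    for path in sorted(directory.glob("band_*.tif")):
        wl = int(path.stem.split("_")[1])
        bands[wl] = tifffile.imread(path).astype(float)
    if not bands:
        raise FileNotFoundError(f"no band_<wavelength>.tif files in {directory}")
    return ReflectanceCube(bands=bands)


def write_tile_images(directory: str | Path, imgs) -> None:
    """Persist one tile acquisition (stacks, target, cube, NIR image)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_frame_stack(directory, imgs.fs_stack)
    write_frame_stack(directory, imgs.sat_stack)
    write_frame_stack(directory, imgs.dark_stack)
    tifffile.imwrite(directory / "target_actinic.tif", imgs.target_actinic.astype(np.float32))
    tifffile.imwrite(directory / "target_saturating.tif", imgs.target_saturating.astype(np.float32))
    write_cube(directory / "cube", imgs.cube)
    tifffile.imwrite(directory / "nir.tif", imgs.nir.astype(np.float32))


def read_tile_images(directory: str | Path) -> dict:
    """Load one tile acquisition back as a dict of arrays/objects."""
    directory = Path(directory)
    out = {
        "fs_stack": read_frame_stack(directory / "actinic_Fs.tif"),
        "sat_stack": read_frame_stack(directory / "saturating.tif"),
        "dark_stack": read_frame_stack(directory / "dark.tif"),
        "target_actinic": tifffile.imread(directory / "target_actinic.tif").astype(float),
        "target_saturating": tifffile.imread(directory / "target_saturating.tif").astype(float),
        "nir": tifffile.imread(directory / "nir.tif").astype(float),
    }
    cube_dir = directory / "cube"
    if cube_dir.exists():
        out["cube"] = read_cube(cube_dir)
    return out
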