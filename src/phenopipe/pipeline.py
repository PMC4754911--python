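"""End-to-end orchestration: fixture images -> per-plant traits -> growth
curves -> heritability, with validation, logging and provenance.

The pipeline is a pure function of (inputs, config, seed): re-running with
the same fixture and configuration reproduces the output CSVs exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imgio
from .fluorescence import compute_phipsii, compute_target_factor, average_frames, select_fm_prime
from .growth import TimeSeries, empirical_slope, fit_pspline, percent_change, relative_growth_rate
from .layout import MeasurementSchedule, load_genotype_map
from .quantgen import estimate_heritability, heritability_timecourse, timecourse_frame
from .segmentation import boxes_from_grid, summarize_plant, threshold_mask, uniform_grid
from .spectral import chlorophyll_index, projected_leaf_area

logger = logging.getLogger("phenopipe")

__all__ = ["RunConfig", "StageError", "validate_inputs", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed after inputs validated cleanly."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``fixture_dir`` must hold a fixture as written by
    :func:`phenopipe.simulate.make_fixture` (manifest, genotype map,
    schedule and -- for the image stages -- per-tile image directories).
    """

    fixture_dir: str
    output_dir: str
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "phipsii": True,
            "spectral": True,
            "segment": True,
            "growth": True,
            "heritability": True,
        }
    )
    threshold: float | str = "auto"
    noise_floor: float = 5.0
    pixel_area_mm2: float | None = None  # derived from plant pitch and box size if None
    spline_lambda: float | None = None   # None = generalized cross-validation
    spline_degree: int = 3
    penalty_order: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def validate_inputs(config: RunConfig) -> list[str]:
    """Pre-flight diagnostics; an empty list means the inputs look clean."""
    diags: list[str] = []
    root = Path(config.fixture_dir)
    if not root.exists():
        return [f"fixture directory not found: {root}"]
    manifest_path = root / "manifest.yaml"
    if not manifest_path.exists():
        diags.append(f"missing manifest: {manifest_path}")
        return diags
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    for rel in ("genotype_map.csv", "schedule.yaml"):
        if not (root / rel).exists():
            diags.append(f"missing fixture file: {rel}")
    if (root / "genotype_map.csv").exists():
        try:
            gmap = load_genotype_map(root / "genotype_map.csv")
        except ValueError as exc:
            diags.append(f"genotype map invalid: {exc}")
        else:
            n_expected = manifest.get("n_plants")
            if n_expected is not None and len(gmap) < n_expected:
                covered = set(gmap.entries)
                missing = sorted(set(range(n_expected)) - covered)[:5]
                diags.append(
                    f"genotype map covers {len(gmap)}/{n_expected} positions "
                    f"(first missing: {missing})"
                )
    for rel in manifest.get("images", []):
        d = root / rel
        if not d.exists():
            diags.append(f"missing image directory: {rel}")
            continue
        try:
            imgs = imgio.read_tile_images(d)
        except (OSError, FileNotFoundError) as exc:
            diags.append(f"unreadable image directory {rel}: {exc}")
            continue
        for key in ("fs_stack", "sat_stack", "dark_stack"):
            stack = imgs[key]
            if not stack.count_matches():
                diags.append(
                    f"{rel}: {stack.role} stack has {len(stack)} frames, "
                    f"expected {stack.expected_count}"
                )
    return diags


def _segment_records(config: RunConfig, root: Path, manifest: dict, gmap) -> pd.DataFrame:
    """Image stages: efficiency, chlorophyll and area per plant, all times."""
    tile_shape = tuple(manifest["layout"]["tile_shape"])
    rows: list[dict] = []
    pos_lookup = {}
    from .layout import build_layout

    layout = build_layout(
        n_tiles=manifest["layout"]["n_tiles"],
        tile_shape=tile_shape,
        tile_grid=tuple(manifest["layout"]["tile_grid"]),
    )
    for p in layout.positions():
        pos_lookup[(p.tile, p.x_within, p.y_within)] = p

    for rel in manifest.get("images", []):
        d = root / rel
        t = float(d.parent.name[1:])
        tile = int(d.name.replace("tile", ""))
        imgs = imgio.read_tile_images(d)
        nir = imgs["nir"]
        grid = uniform_grid(nir.shape, tile_shape)
        boxes = boxes_from_grid(grid, nir.shape, expected_shape=tile_shape)

        phi = None
        if config.stages.get("phipsii", True):
            corr = compute_target_factor(
                imgs["target_actinic"],
                imgs["target_saturating"],
                np.ones(imgs["target_actinic"].shape, dtype=bool),
            )
            fs = average_frames(imgs["fs_stack"])
            fm = select_fm_prime(imgs["sat_stack"])
            dark = average_frames(imgs["dark_stack"])
            phi = compute_phipsii(fs, fm, dark, corr, noise_floor=config.noise_floor)
            fm_signal = fm - dark
        chl = None
        if config.stages.get("spectral", True) and "cube" in imgs:
            chl = chlorophyll_index(imgs["cube"])

        pitch = layout.plant_pitch_mm
        box_px = boxes[0].shape[0]
        pixel_area = config.pixel_area_mm2 or (pitch / box_px) ** 2

        for i, box in enumerate(boxes):
            xw, yw = divmod(i, tile_shape[1])
            pos = pos_lookup[(tile, xw, yw)]
            entry = gmap[pos.index]
            meta = dict(
                genotype=entry.genotype,
                experiment=entry.experiment,
                basin=entry.basin,
                tile=tile,
                x=pos.x,
                y=pos.y,
                x_within=xw,
                y_within=yw,
                time_h=t,
            )
            nir_mask = threshold_mask(nir, box, config.threshold)
            area = projected_leaf_area(nir, nir_mask.full_frame(nir.shape), pixel_area)
            rows.append(
                dict(meta, trait="pla", value=area.area_mm2, n_pixels=area.pixel_count,
                     is_check=entry.is_check)
            )
            if phi is not None:
                # efficiency pixels are selected with a mask from the
                # fluorescence signal itself (Fm' image), not the NIR mask
                phi_mask = threshold_mask(fm_signal, box, config.threshold)
                rec = summarize_plant(phi.values, phi_mask, trait="phipsii", **{})
                rows.append(
                    dict(meta, trait="phipsii", value=rec.mean_value,
                         n_pixels=rec.n_pixels, is_check=entry.is_check)
                )
            if chl is not None:
                rec = summarize_plant(chl.values, nir_mask)
                rows.append(
                    dict(meta, trait="chl", value=rec.mean_value,
                         n_pixels=rec.n_pixels, is_check=entry.is_check)
                )
    return pd.DataFrame(rows)


def _growth_outputs(config: RunConfig, table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    pla = table[table["trait"] == "pla"]
    for (tile, xw, yw), grp in pla.groupby(["tile", "x_within", "y_within"]):
        grp = grp.sort_values("time_h")
        series = TimeSeries(grp["time_h"].to_numpy(), grp["value"].to_numpy())
        t_later, pct = percent_change(series)
        pct_map = dict(zip(t_later, pct))
        min_pts = config.spline_degree + 2
        if len(series) >= min_pts and np.all(series.values > 0):
            fit = fit_pspline(
                series,
                degree=config.spline_degree,
                penalty_order=config.penalty_order,
                lam=config.spline_lambda,
            )
            slopes = empirical_slope(fit, series.times)
            rgr = relative_growth_rate(fit, series.times)
            fitted = fit.fitted
        else:
            logger.warning(
                "plant (%s,%s,%s): %d points, growth curve skipped", tile, xw, yw, len(series)
            )
            slopes = rgr = fitted = [np.nan] * len(series)
        for i, t in enumerate(series.times):
            rows.append(
                {
                    "tile": tile,
                    "x_within": xw,
                    "y_within": yw,
                    "genotype": grp["genotype"].iloc[0],
                    "time_h": t,
                    "pla": series.values[i],
                    "fitted": fitted[i],
                    "slope": slopes[i],
                    "rgr": rgr[i],
                    "pct_change_3h": pct_map.get(t, np.nan),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages in dependency order; returns the run report.

    Raises ``FileNotFoundError``/``ValueError`` before any stage runs when
    inputs do not validate, and :class:`StageError` when a stage fails.
    """
    t0 = _time.time()
    diags = validate_inputs(config)
    hard = [d for d in diags if not d.startswith("warning")]
    if hard and any("missing" in d or "not found" in d or "invalid" in d for d in hard):
        raise FileNotFoundError("; ".join(hard))

    root = Path(config.fixture_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"diagnostics": diags, "stages": {}, "outputs": []}
    try:
        with open(root / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)
        gmap = load_genotype_map(root / "genotype_map.csv")
        schedule = MeasurementSchedule.from_yaml(root / "schedule.yaml")

        if config.stages.get("segment", True) and manifest.get("images"):
            t_stage = _time.time()
            table = _segment_records(config, root, manifest, gmap)
            table.to_csv(out / "plant_records.csv", index=False)
            report["outputs"].append("plant_records.csv")
            report["stages"]["segment"] = {
                "n_records": len(table),
                "seconds": _time.time() - t_stage,
            }
            logger.info("segment: %d records", len(table))
        elif (root / "table.csv").exists():
            table = pd.read_csv(root / "table.csv")
            report["stages"]["segment"] = {"skipped": True, "source": "table.csv"}
        else:
            raise StageError("segment stage disabled and no precomputed table.csv available")

        if config.stages.get("growth", True):
            t_stage = _time.time()
            growth = _growth_outputs(config, table)
            growth.to_csv(out / "growth_curves.csv", index=False)
            report["outputs"].append("growth_curves.csv")
            report["stages"]["growth"] = {
                "n_plants": growth.groupby(["tile", "x_within", "y_within"]).ngroups if len(growth) else 0,
                "seconds": _time.time() - t_stage,
            }

        if config.stages.get("heritability", True):
            t_stage = _time.time()
            frames = []
            for trait in sorted(table["trait"].unique()):
                try:
                    ests = heritability_timecourse(table, trait, schedule=schedule)
                except ValueError as exc:
                    logger.warning("heritability for %s skipped: %s", trait, exc)
                    continue
                frames.append(timecourse_frame(ests))
            if frames:
                h2 = pd.concat(frames, ignore_index=True)
                h2.to_csv(out / "heritability.csv", index=False)
                report["outputs"].append("heritability.csv")
                report["stages"]["heritability"] = {
                    "n_estimates": len(h2),
                    "seconds": _time.time() - t_stage,
                }

        report["traits"] = sorted(table["trait"].unique())
        report["n_genotypes"] = int(table["genotype"].nunique())
        report["n_time_points"] = int(table["time_h"].nunique())
        report["seconds"] = _time.time() - t0
        config.to_yaml(out / "resolved_config.yaml")
        with open(out / "report.yaml", "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=True)
    except StageError:
        raise
    except (ValueError, KeyError, RuntimeError) as exc:
        raise StageError(str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return report
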