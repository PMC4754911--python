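"""Virtual phenotyping-platform experiments with known ground truth.

The generator emulates a complete screening run: genotypes laid out on the
tile grid, trait values built from the additive design model (overall mean
+ genotype + experiment + basin + platform row/column + tile + within-tile
row/column + interactions + residual), projected leaf area following a
logistic growth law modulated by a diel leaf-movement sinusoid, and --
optionally -- rendered camera images (fluorescence frame stacks,
reflectance cubes, near-infrared images) from which every stage of the
image pipeline can be validated against the exact values used to draw
them.

Simulated photosystem II efficiency sits near the observed natural range
(about 0.62-0.72 at 200 umol m-2 s-1 growth light, lower at 550); optional
"extreme" genotypes emulate an atrazine-resistant accession with very low
efficiency (mean 0.35) and a mutant showing a daily within-photoperiod
decline.  Genotypic variance can be modulated sinusoidally over the day to
create a programmed heritability time course for recovery experiments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .fluorescence import FrameStack
from .layout import (
    GenotypeEntry,
    GenotypeMap,
    MeasurementSchedule,
    PlatformLayout,
    build_layout,
    default_schedule,
)
from .spectral import ReflectanceCube

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TileImages",
    "simulate_phenotypes",
    "render_tile_images",
    "make_fixture",
    "SCENARIOS",
]

ELY_LIKE = "Ely-like"
BC354_LIKE = "BC354-like"


def _default_variances() -> dict[str, dict[str, float]]:
    # per-trait variance maps for the design-model terms, trait units^2
    return {
        "phipsii": {
            "genotype": 6.25e-4,       # SD 0.025 across genotypes
            "experiment": 4.0e-4,      # substantial main effect of run
            "basin": 2.5e-5,
            "x": 2.5e-5,
            "y": 2.5e-5,
            "tile": 2.5e-5,
            "x_within": 2.0e-4,        # light gradient inside the camera head
            "y_within": 2.0e-4,
            "genotype:experiment": 0.0,  # negligible G x E by default
            "residual": 6.25e-4,       # same order as the genotypic variance
        },
        "chl": {
            "genotype": 0.04,
            "experiment": 0.02,
            "basin": 1e-3,
            "x": 1e-3,
            "y": 1e-3,
            "tile": 1e-3,
            "x_within": 4e-3,
            "y_within": 4e-3,
            "genotype:experiment": 0.0,
            "residual": 0.04,
        },
    }


@dataclass
class SimulationConfig:
    """All knobs of the virtual experiment.

    The defaults encode the study conditions the rest of the package is
    tested under: 20 genotypes x 4 replicates in one experiment, a 10-h
    photoperiod, growth light of 200 umol m-2 s-1, genotypic and residual
    efficiency variance of the same order, negligible genotype-by-design
    interactions, and a 5 % leaf-movement amplitude that halves at high
    light.
    """

    n_genotypes: int = 20
    n_replicates: int = 4
    n_experiments: int = 1
    n_check_genotypes: int = 0
    check_replicates: int = 4
    light_umol: float = 200.0
    include_extremes: bool = False
    variances: dict[str, dict[str, float]] = field(default_factory=_default_variances)
    # efficiency model
    phipsii_mean_200: float = 0.67
    phipsii_mean_550: float = 0.585
    phipsii_diel_amplitude: float = 0.01
    ely_phipsii_mean: float = 0.35
    bc354_daily_decline_per_h: float = 0.015
    genotype_modulation_amp: float = 0.0   # sinusoidal sigma_G(t) modulation
    # chlorophyll-index model (decreases with growth irradiance)
    chl_mean_200: float = 2.0
    chl_mean_550: float = 1.6
    # growth model (logistic, per plant); measurements start start_day days
    # after sowing, once rosettes are large enough to segment reliably
    start_day: int = 14
    initial_area_mm2: float = 5.0
    growth_rate_per_h: float = 0.008
    growth_rate_cv: float = 0.08          # genotypic CV of the growth rate
    area_cap_mm2: float = 2000.0
    pla_residual_cv: float = 0.03
    movement_amplitude_pct: float = 5.0   # night-time amplitude, % of PLA
    movement_day_fraction: float = 0.5    # day amplitude relative to night
    # image rendering
    box_px: int = 50
    fm_level: float = 400.0
    dark_level: float = 10.0
    lamp_ratio: float = 1.0
    target_level: float = 300.0
    read_noise: float = 2.0
    reflectance_noise: float = 0.002
    nir_plant_level: float = 200.0
    nir_background_level: float = 5.0
    r790_plant: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for trait, vs in self.variances.items():
            bad = {k: v for k, v in vs.items() if v < 0}
            if bad:
                raise ValueError(f"negative variance(s) for {trait}: {bad}")
        if not 0 <= self.movement_amplitude_pct < 50:
            raise ValueError("movement_amplitude_pct must lie in [0, 50)")

    @property
    def phipsii_mean(self) -> float:
        return self.phipsii_mean_200 if self.light_umol <= 350 else self.phipsii_mean_550

    @property
    def chl_mean(self) -> float:
        return self.chl_mean_200 if self.light_umol <= 350 else self.chl_mean_550

    @property
    def movement_amplitude(self) -> float:
        amp = self.movement_amplitude_pct / 100.0
        return amp if self.light_umol <= 350 else amp / 2.0


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would have to estimate."""

    phenotypes: pd.DataFrame       # plant x time x trait, true (noise-free) + observed
    genotype_effects: pd.DataFrame
    timecourse: pd.DataFrame       # programmed sigma2_G(t) and H2(t) for phipsii
    config: SimulationConfig
    layout: PlatformLayout
    schedule: MeasurementSchedule
    genotype_map: GenotypeMap


def _genotype_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    base = [f"G{i:03d}" for i in range(1, config.n_genotypes + 1)]
    if config.include_extremes:
        base = base + [ELY_LIKE, BC354_LIKE]
    checks = [f"CHK{i}" for i in range(1, config.n_check_genotypes + 1)]
    return base, checks


def _assign_positions(
    config: SimulationConfig, layout: PlatformLayout, rng: np.random.Generator
) -> pd.DataFrame:
    """Randomised assignment of genotypes to platform positions, per experiment."""
    genotypes, checks = _genotype_names(config)
    plant_list = [(g, False) for g in genotypes for _ in range(config.n_replicates)]
    plant_list += [(g, True) for g in checks for _ in range(config.check_replicates)]
    if len(plant_list) > layout.n_plants:
        raise ValueError(
            f"{len(plant_list)} plants do not fit the {layout.n_plants}-position layout"
        )
    pos_frame = layout.to_frame()
    rows = []
    for e in range(config.n_experiments):
        order = rng.permutation(layout.n_plants)[: len(plant_list)]
        shuffled = rng.permutation(len(plant_list))
        for slot, (gi, pos_i) in enumerate(zip(shuffled, order)):
            g, is_check = plant_list[gi]
            p = pos_frame.iloc[pos_i]
            rows.append(
                {
                    "experiment": f"E{e + 1}",
                    "position": int(p["index"]),
                    "tile": int(p["tile"]),
                    "x": int(p["x"]),
                    "y": int(p["y"]),
                    "x_within": int(p["x_within"]),
                    "y_within": int(p["y_within"]),
                    "basin": f"B{int(p['basin']) + 1}",
                    "genotype": g,
                    "is_check": is_check,
                }
            )
    return pd.DataFrame(rows)


def _draw_levels(levels, var: float, rng: np.random.Generator) -> dict:
    sd = math.sqrt(var)
    return {lv: rng.normal(0.0, sd) if sd > 0 else 0.0 for lv in levels}


def _measurement_times(
    schedule: MeasurementSchedule, n_days: int, tasks, start_day: int = 0
) -> list[float]:
    return [
        24.0 * (start_day + d) + t
        for d in range(n_days)
        for t, task in schedule.events
        if task in tasks
    ]


def simulate_phenotypes(
    config: SimulationConfig,
    layout: PlatformLayout | None = None,
    schedule: MeasurementSchedule | None = None,
    n_days: int = 3,
    traits: tuple[str, ...] = ("phipsii", "chl", "pla"),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a full phenotype table plus its ground truth.

    Efficiency and chlorophyll index follow the additive design model;
    projected leaf area follows a per-plant logistic growth curve times a
    day/night-gated leaf-movement sinusoid with multiplicative residual
    noise.  Everything is deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if layout is None:
        genotypes, checks = _genotype_names(config)
        n_plants = config.n_replicates * len(genotypes) + config.check_replicates * len(checks)
        layout = build_layout(n_tiles=max(1, -(-n_plants // 12)))
    if schedule is None:
        schedule = default_schedule()

    plants = _assign_positions(config, layout, rng)
    genotypes, checks = _genotype_names(config)
    all_geno = genotypes + checks

    # --- genotype effects ------------------------------------------------
    phi_vs = config.variances["phipsii"]
    chl_vs = config.variances["chl"]
    g_phi = _draw_levels(all_geno, phi_vs["genotype"], rng)
    g_chl = _draw_levels(all_geno, chl_vs["genotype"], rng)
    g_rate = {
        g: config.growth_rate_per_h
        * (1.0 + (rng.normal(0.0, config.growth_rate_cv) if config.growth_rate_cv else 0.0))
        for g in all_geno
    }
    if config.include_extremes:
        g_phi[ELY_LIKE] = config.ely_phipsii_mean - config.phipsii_mean
        g_phi[BC354_LIKE] = 0.0  # its anomaly is the daily decline, not the mean

    # --- design effects (per experiment where the model crosses them) ----
    exps = sorted(plants["experiment"].unique())
    eff = {
        "experiment": _draw_levels(exps, phi_vs["experiment"] if len(exps) > 1 else 0.0, rng),
    }
    chl_eff = {
        "experiment": _draw_levels(exps, chl_vs["experiment"] if len(exps) > 1 else 0.0, rng),
    }
    for term, levels in (
        ("basin", sorted(plants["basin"].unique())),
        ("x", sorted(plants["x"].unique())),
        ("y", sorted(plants["y"].unique())),
        ("tile", sorted(plants["tile"].unique())),
        ("x_within", sorted(plants["x_within"].unique())),
        ("y_within", sorted(plants["y_within"].unique())),
    ):
        eff[term] = _draw_levels(levels, phi_vs[term], rng)
        chl_eff[term] = _draw_levels(levels, chl_vs[term], rng)
    gxe_levels = [(g, e) for g in all_geno for e in exps]
    eff_gxe = _draw_levels(gxe_levels, phi_vs.get("genotype:experiment", 0.0), rng)
    chl_gxe = _draw_levels(gxe_levels, chl_vs.get("genotype:experiment", 0.0), rng)

    growth_light_boost = 1.0 if config.light_umol <= 350 else 1.3
    day_amp = config.movement_amplitude * config.movement_day_fraction
    night_amp = config.movement_amplitude

    def design_sum(effmap, row) -> float:
        return (
            effmap["experiment"][row.experiment]
            + effmap["basin"][row.basin]
            + effmap["x"][row.x]
            + effmap["y"][row.y]
            + effmap["tile"][row.tile]
            + effmap["x_within"][row.x_within]
            + effmap["y_within"][row.y_within]
        )

    def gmod(t: float) -> float:
        return 1.0 + config.genotype_modulation_amp * math.sin(2 * math.pi * t / 24.0)

    phi_times = _measurement_times(schedule, n_days, {"phipsii"}, config.start_day)
    chl_times = _measurement_times(
        schedule,
        n_days,
        {"spectral"} if daily_spectral(schedule) else {"phipsii"},
        config.start_day,
    )
    pla_times = _measurement_times(schedule, n_days, {"phipsii", "nir"}, config.start_day)

    records: list[dict] = []
    sd_phi_e = math.sqrt(phi_vs["residual"])
    sd_chl_e = math.sqrt(chl_vs["residual"])
    for row in plants.itertuples():
        base_phi = config.phipsii_mean + design_sum(eff, row) + eff_gxe[(row.genotype, row.experiment)]
        base_chl = config.chl_mean + design_sum(chl_eff, row) + chl_gxe[(row.genotype, row.experiment)]
        rate = g_rate[row.genotype] * growth_light_boost
        if "phipsii" in traits:
            for t in phi_times:
                diel = config.phipsii_diel_amplitude * math.sin(
                    2 * math.pi * (t % 24.0) / 24.0
                )
                true = base_phi + g_phi[row.genotype] * gmod(t) + diel
                if config.include_extremes and row.genotype == BC354_LIKE:
                    if schedule.is_day(t):
                        true -= config.bc354_daily_decline_per_h * (t % 24.0)
                true = min(max(true, 0.0), 1.0)
                records.append(
                    _rec(row, t, "phipsii", true, true + rng.normal(0.0, sd_phi_e))
                )
        if "chl" in traits:
            for t in chl_times:
                true = base_chl + g_chl[row.genotype]
                records.append(
                    _rec(row, t, "chl", true, true + rng.normal(0.0, sd_chl_e))
                )
        if "pla" in traits:
            for t in pla_times:
                true = _logistic_area(
                    config.initial_area_mm2, rate, config.area_cap_mm2, t
                )
                amp = day_amp if schedule.is_day(t) else night_amp
                true *= 1.0 + amp * math.sin(2 * math.pi * (t % 24.0) / 24.0)
                obs = true * (1.0 + rng.normal(0.0, config.pla_residual_cv))
                records.append(_rec(row, t, "pla", true, max(obs, 0.0)))

    pheno = pd.DataFrame(records)
    table = pheno.drop(columns=["true_value"]).rename(columns={"observed": "value"})

    sigma2_g = phi_vs["genotype"]
    sigma2_e = phi_vs["residual"]
    # realized genotypic variance: the sample variance of the effects that
    # were actually drawn for this experiment -- this is the quantity an
    # ANOVA on the data estimates, and differs from the nominal sigma2_G by
    # the genotype-sampling noise (a chi-square_{k-1}/(k-1) factor)
    drawn = np.array([g_phi[g] for g in genotypes])
    sigma2_g_real = float(np.var(drawn, ddof=1)) if len(drawn) > 1 else 0.0
    tc_rows = []
    for t in sorted(set(phi_times)):
        s2g_t = sigma2_g * gmod(t) ** 2
        s2g_real_t = sigma2_g_real * gmod(t) ** 2
        tc_rows.append(
            {
                "time_h": t,
                "is_day": schedule.is_day(t),
                "sigma2_G": s2g_t,
                "sigma2_G_realized": s2g_real_t,
                "sigma2_E": sigma2_e,
                "H2": s2g_t / (s2g_t + sigma2_e) if s2g_t + sigma2_e > 0 else 0.0,
                "H2_realized": (
                    s2g_real_t / (s2g_real_t + sigma2_e)
                    if s2g_real_t + sigma2_e > 0
                    else 0.0
                ),
            }
        )

    gmap = GenotypeMap(
        {
            int(r.position): GenotypeEntry(
                genotype=r.genotype,
                experiment=r.experiment,
                basin=r.basin,
                is_check=bool(r.is_check),
            )
            for r in plants[plants["experiment"] == exps[0]].itertuples()
        }
    )
    truth = GroundTruth(
        phenotypes=pheno,
        genotype_effects=pd.DataFrame(
            {
                "genotype": all_geno,
                "phipsii_effect": [g_phi[g] for g in all_geno],
                "chl_effect": [g_chl[g] for g in all_geno],
                "growth_rate_per_h": [g_rate[g] for g in all_geno],
            }
        ),
        timecourse=pd.DataFrame(tc_rows),
        config=config,
        layout=layout,
        schedule=schedule,
        genotype_map=gmap,
    )
    return table, truth


def daily_spectral(schedule: MeasurementSchedule) -> bool:
    return any(task == "spectral" for _, task in schedule.events)


def _logistic_area(a0: float, rate: float, cap: float, t: float) -> float:
    if a0 <= 0:
        return 0.0
    return cap * a0 / (a0 + (cap - a0) * math.exp(-rate * t))


def _rec(row, t: float, trait: str, true: float, obs: float) -> dict:
    return {
        "experiment": row.experiment,
        "position": row.position,
        "tile": row.tile,
        "x": row.x,
        "y": row.y,
        "x_within": row.x_within,
        "y_within": row.y_within,
        "basin": row.basin,
        "genotype": row.genotype,
        "is_check": row.is_check,
        "time_h": t,
        "trait": trait,
        "true_value": true,
        "observed": obs,
    }


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

@dataclass
class TileImages:
    """Rendered camera output for one tile at one time point."""

    fs_stack: FrameStack
    sat_stack: FrameStack
    dark_stack: FrameStack
    target_actinic: np.ndarray
    target_saturating: np.ndarray
    target_region: np.ndarray
    cube: ReflectanceCube
    nir: np.ndarray
    true_mask: np.ndarray
    true_values: pd.DataFrame  # per-plant truths used for drawing


def _rose_mask(shape: tuple[int, int], area_px: float, lobes: int = 8, depth: float = 0.25) -> np.ndarray:
    """Rasterise a lobed-rosette silhouette of (approximately) a given area."""
    mask = np.zeros(shape, dtype=bool)
    if area_px <= 0:
        return mask
    # area of r = r0 (1 + depth cos(k theta)) is pi r0^2 (1 + depth^2 / 2)
    r0 = math.sqrt(area_px / (math.pi * (1 + depth**2 / 2)))
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r_max = min(shape) / 2.0 - 1.0
    if r0 * (1 + depth) > r_max:
        warnings.warn("plant area exceeds its box; silhouette clipped")
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    bound = np.minimum(r0 * (1 + depth * np.cos(lobes * theta)), r_max)
    return rr <= bound


def render_tile_images(
    truth: GroundTruth,
    tile: int,
    time_h: float,
    experiment: str | None = None,
    source: str = "true",
    rng: np.random.Generator | None = None,
) -> TileImages:
    """Render the camera images for one tile at one measurement time.

    Fluorescence stacks are built so that the fluorescence pipeline
    recovers the plant's efficiency exactly in the noiseless case: on-plant
    maximal fluorescence is ``fm_level`` counts, steady-state fluorescence
    is ``fm_level * (1 - phi)``, frames are recorded with the configured
    dark offset and actinic/saturating lamp-intensity ratio, and the
    fluorescent target patch encodes that ratio.  Reflectance bands encode
    the chlorophyll index through the red-edge formula inverted at fixed
    790-nm reflectance.  ``source`` selects whether the drawn values are
    the noise-free truths (``"true"``) or the observed table values
    (``"observed"``); ``rng=None`` renders without read noise.
    """
    cfg = truth.config
    ph = truth.phenotypes
    if experiment is None:
        experiment = sorted(ph["experiment"].unique())[0]
    col = "true_value" if source == "true" else "observed"
    sel = ph[
        (ph["tile"] == tile)
        & np.isclose(ph["time_h"].astype(float), time_h)
        & (ph["experiment"] == experiment)
    ]
    if sel.empty:
        raise ValueError(f"ground truth does not cover tile {tile} at t={time_h}")
    per_plant = sel.pivot_table(
        index=["x_within", "y_within", "genotype"], columns="trait", values=col
    ).reset_index()

    tr, tc = truth.layout.tile_shape
    box = cfg.box_px
    shape = (tr * box, tc * box)
    pitch_px = cfg.box_px
    pixel_area = (truth.layout.plant_pitch_mm / pitch_px) ** 2

    phi_img = np.zeros(shape)
    chl_img = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    for r in per_plant.itertuples():
        area_mm2 = getattr(r, "pla", 0.0) if hasattr(r, "pla") else 0.0
        area_px = float(area_mm2) / pixel_area if np.isfinite(area_mm2) else 0.0
        pm = _rose_mask((box, box), area_px)
        r0, c0 = int(r.x_within) * box, int(r.y_within) * box
        sub = (slice(r0, r0 + box), slice(c0, c0 + box))
        mask[sub] |= pm
        if hasattr(r, "phipsii") and np.isfinite(getattr(r, "phipsii", np.nan)):
            phi_img[sub][pm] = float(r.phipsii)
        if hasattr(r, "chl") and np.isfinite(getattr(r, "chl", np.nan)):
            chl_img[sub][pm] = float(r.chl)

    noise = (lambda s: rng.normal(0.0, cfg.read_noise, s)) if rng is not None else (lambda s: 0.0)

    fm_true = np.where(mask, cfg.fm_level, 0.0)
    fs_true = fm_true * (1.0 - phi_img)
    fs_recorded = fs_true / cfg.lamp_ratio + cfg.dark_level
    fm_recorded = fm_true + cfg.dark_level

    fs_frames = np.stack([fs_recorded + noise(shape) for _ in range(24)])
    sat_scales = (0.75, 0.88, 1.0, 0.94, 0.86, 0.78)
    sat_frames = np.stack(
        [s * fm_true + cfg.dark_level + noise(shape) for s in sat_scales]
    )
    dark_frames = np.stack([cfg.dark_level + np.zeros(shape) + noise(shape) for _ in range(24)])

    tgt_shape = (8, 8)
    target_region = np.ones(tgt_shape, dtype=bool)
    target_act = np.full(tgt_shape, cfg.target_level / cfg.lamp_ratio) + noise(tgt_shape)
    target_sat = np.full(tgt_shape, cfg.target_level) + noise(tgt_shape)

    r790 = np.where(mask, cfg.r790_plant, 0.02)
    with np.errstate(divide="ignore"):
        r700 = np.where(mask, cfg.r790_plant / (1.0 + chl_img), 0.02)
    leaf_spectrum = {480: 0.05, 532: 0.12, 550: 0.15, 570: 0.13, 660: 0.06, 750: 0.45}
    bands = {}
    for wl, level in leaf_spectrum.items():
        bands[wl] = np.where(mask, level, 0.02)
    bands[700] = r700
    bands[790] = r790
    if rng is not None and cfg.reflectance_noise > 0:
        for wl in bands:
            bands[wl] = np.clip(
                bands[wl] + rng.normal(0.0, cfg.reflectance_noise, shape), 0.0, 1.0
            )
    cube = ReflectanceCube(bands=bands)

    nir = np.where(mask, cfg.nir_plant_level, cfg.nir_background_level) + noise(shape)
    nir = np.clip(nir, 0.0, None)

    return TileImages(
        fs_stack=FrameStack(np.clip(fs_frames, 0, None), role="actinic_Fs"),
        sat_stack=FrameStack(np.clip(sat_frames, 0, None), role="saturating"),
        dark_stack=FrameStack(np.clip(dark_frames, 0, None), role="dark"),
        target_actinic=np.clip(target_act, 0, None),
        target_saturating=np.clip(target_sat, 0, None),
        target_region=target_region,
        cube=cube,
        nir=nir,
        true_mask=mask,
        true_values=per_plant,
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

SCENARIOS = ("minimal", "paperlike", "extremes")


def _scenario_config(name: str, seed: int) -> tuple[SimulationConfig, PlatformLayout, int]:
    if name == "minimal":
        cfg = SimulationConfig(n_genotypes=2, n_replicates=6, seed=seed)
        return cfg, build_layout(n_tiles=1), 1
    if name in ("paperlike", "extremes"):
        cfg = SimulationConfig(
            n_genotypes=20,
            n_replicates=72,
            include_extremes=(name == "extremes"),
            seed=seed,
        )
        return cfg, build_layout(n_tiles=120), 4
    raise ValueError(f"unknown scenario {name!r}; choose one of {SCENARIOS}")


def make_fixture(
    name: str,
    out_dir,
    seed: int = 0,
    write_images: bool | None = None,
    n_days: int | None = None,
) -> dict:
    """Write a complete on-disk fixture for a named scenario.

    Scenarios: ``minimal`` (1 tile, 2 genotypes, 3 efficiency time points,
    with images), ``paperlike`` (the full 120-tile, 1440-plant platform over
    several days; tables only by default) and ``extremes`` (paperlike plus
    the two extreme genotypes).  Returns the manifest dictionary; the same
    seed always produces byte-identical CSVs.
    """
    from pathlib import Path

    from . import imgio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg, layout, default_days = _scenario_config(name, seed)
    days = n_days if n_days is not None else default_days
    if write_images is None:
        write_images = name == "minimal"
    schedule = default_schedule()
    table, truth = simulate_phenotypes(cfg, layout=layout, schedule=schedule, n_days=days)

    truth.genotype_map.write_csv(out / "genotype_map.csv")
    table.to_csv(out / "table.csv", index=False)
    (out / "truth").mkdir(exist_ok=True)
    truth.phenotypes.to_csv(out / "truth" / "phenotypes.csv", index=False)
    truth.timecourse.to_csv(out / "truth" / "timecourse.csv", index=False)
    truth.genotype_effects.to_csv(out / "truth" / "genotype_effects.csv", index=False)
    schedule.to_yaml(out / "schedule.yaml")

    phi_times = sorted(
        truth.phenotypes.loc[truth.phenotypes["trait"] == "phipsii", "time_h"].unique()
    )
    image_entries = []
    if write_images:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 777]).generate_state(1)[0])
        for t in phi_times:
            for tile in sorted(truth.phenotypes["tile"].unique()):
                imgs = render_tile_images(truth, int(tile), float(t), rng=rng)
                d = out / "images" / f"t{t:07.2f}" / f"tile{int(tile):03d}"
                imgio.write_tile_images(d, imgs)
                image_entries.append(str(d.relative_to(out)))

    manifest = {
        "scenario": name,
        "seed": seed,
        "n_days": days,
        "n_plants": int(layout.n_plants),
        "n_genotypes": len(_genotype_names(cfg)[0]),
        "layout": {
            "tile_grid": list(layout.tile_grid),
            "tile_shape": list(layout.tile_shape),
            "n_tiles": layout.n_tiles,
        },
        "mask_bearing_images_per_day": sum(
            1 for _, task in schedule.events if task in ("nir", "phipsii")
        ),
        "phi_times": [float(t) for t in phi_times],
        "images": image_entries,
        "files": ["genotype_map.csv", "table.csv", "truth/phenotypes.csv",
                  "truth/timecourse.csv", "truth/genotype_effects.csv", "schedule.yaml"],
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
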