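import numpy as np
import pandas as pd
import pytest
import yaml

from phenopipe.fluorescence import (
    average_frames,
    compute_phipsii,
    compute_target_factor,
    select_fm_prime,
)
from phenopipe.segmentation import boxes_from_grid, threshold_mask, uniform_grid
from phenopipe.simulate import (
    SimulationConfig,
    _default_variances,
    make_fixture,
    render_tile_images,
    simulate_phenotypes,
)
from phenopipe.spectral import chlorophyll_index, projected_leaf_area


def flat_config(seed=0, **kw):
    """Config with all variances zeroed; every observation equals the mean."""
    v = _default_variances()
    for trait in v:
        for k in v[trait]:
            v[trait][k] = 0.0
    defaults = dict(
        variances=v, phipsii_diel_amplitude=0.0, growth_rate_cv=0.0,
        pla_residual_cv=0.0, movement_amplitude_pct=0.0, seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulatePhenotypes:
    def test_all_variances_zero_every_value_is_the_mean(self):
        cfg = flat_config()
        table, _ = simulate_phenotypes(cfg, n_days=1, traits=("phipsii",))
        np.testing.assert_allclose(table["value"], cfg.phipsii_mean, atol=1e-12)

    def test_genotype_only_variance_makes_within_genotype_identical(self):
        cfg = flat_config(n_genotypes=2, n_replicates=6)
        cfg.variances["phipsii"]["genotype"] = 1e-3
        table, _ = simulate_phenotypes(cfg, n_days=1, traits=("phipsii",))
        t0 = table[table.time_h == table.time_h.min()]
        for _, grp in t0.groupby("genotype"):
            assert grp["value"].nunique() == 1
        assert t0.groupby("genotype")["value"].mean().nunique() == 2

    def test_variance_decomposition_matches_configuration(self):
        # law of total variance over many seeds: the observed between-plant
        # variance matches the summed configured components, each corrected
        # by (1 - 1/L) for the finite number of factor levels realised
        v = _default_variances()["phipsii"]
        samples = []
        expected = None
        for seed in range(40):
            table, _ = simulate_phenotypes(
                SimulationConfig(seed=seed, phipsii_diel_amplitude=0.0),
                n_days=1, traits=("phipsii",),
            )
            t0 = table[table.time_h == table.time_h.min()]
            if expected is None:
                expected = v["residual"] + sum(
                    v[term] * (1.0 - 1.0 / t0[term].nunique())
                    for term in ("genotype", "basin", "x", "y", "tile", "x_within", "y_within")
                )
            samples.append(t0["value"].var(ddof=1))
        assert np.mean(samples) == pytest.approx(expected, rel=0.10)

    def test_seed_determinism_and_divergence(self):
        t1, _ = simulate_phenotypes(SimulationConfig(seed=5), n_days=1)
        t2, _ = simulate_phenotypes(SimulationConfig(seed=5), n_days=1)
        t3, _ = simulate_phenotypes(SimulationConfig(seed=6), n_days=1)
        pd.testing.assert_frame_equal(t1, t2)
        assert not np.allclose(t1["value"], t3["value"])

    def test_light_level_shifts_efficiency_and_chlorophyll_down(self):
        lo, _ = simulate_phenotypes(flat_config(light_umol=200), n_days=1)
        hi, _ = simulate_phenotypes(flat_config(light_umol=550), n_days=1)
        for trait in ("phipsii", "chl"):
            assert (
                lo.loc[lo.trait == trait, "value"].mean()
                > hi.loc[hi.trait == trait, "value"].mean()
            )

    def test_negative_variance_rejected(self):
        v = _default_variances()
        v["phipsii"]["genotype"] = -1.0
        with pytest.raises(ValueError):
            SimulationConfig(variances=v)

    def test_bc354_like_declines_within_photoperiod(self):
        cfg = flat_config(include_extremes=True, n_genotypes=3)
        table, _ = simulate_phenotypes(cfg, n_days=1, traits=("phipsii",))
        bc = table[table.genotype == "BC354-like"].groupby("time_h")["value"].mean()
        assert bc.is_monotonic_decreasing
        ely = table[table.genotype == "Ely-like"]["value"].mean()
        assert ely == pytest.approx(cfg.ely_phipsii_mean, abs=0.02)


@pytest.fixture(scope="module")
def truth():
    cfg = SimulationConfig(n_genotypes=2, n_replicates=6, seed=21, lamp_ratio=2.0)
    _, truth = simulate_phenotypes(cfg, n_days=1)
    return truth


class TestRenderRoundTrip:
    @staticmethod
    def _phi_time(truth):
        ph = truth.phenotypes
        return float(ph.loc[ph.trait == "phipsii", "time_h"].min())

    def test_noiseless_phipsii_recovered_exactly(self, truth):
        t0 = self._phi_time(truth)
        imgs = render_tile_images(truth, 0, t0)  # rng=None: noiseless
        corr = compute_target_factor(
            imgs.target_actinic, imgs.target_saturating, imgs.target_region
        )
        assert corr.factor == pytest.approx(truth.config.lamp_ratio, abs=1e-12)
        phi = compute_phipsii(
            average_frames(imgs.fs_stack),
            select_fm_prime(imgs.sat_stack),
            average_frames(imgs.dark_stack),
            corr,
        )
        grid = uniform_grid(imgs.nir.shape, (3, 4))
        for i, box in enumerate(boxes_from_grid(grid, imgs.nir.shape)):
            xw, yw = divmod(i, 4)
            row = imgs.true_values[
                (imgs.true_values.x_within == xw) & (imgs.true_values.y_within == yw)
            ]
            patch = phi.values[box.slice()]
            sel = imgs.true_mask[box.slice()]
            assert np.nanmax(np.abs(patch[sel] - float(row["phipsii"].iloc[0]))) <= 1e-9

    def test_noiseless_chl_recovered_exactly(self, truth):
        t0 = self._phi_time(truth)
        imgs = render_tile_images(truth, 0, t0)
        chl = chlorophyll_index(imgs.cube)
        grid = uniform_grid(imgs.nir.shape, (3, 4))
        for i, box in enumerate(boxes_from_grid(grid, imgs.nir.shape)):
            xw, yw = divmod(i, 4)
            row = imgs.true_values[
                (imgs.true_values.x_within == xw) & (imgs.true_values.y_within == yw)
            ]
            sel = imgs.true_mask[box.slice()]
            vals = chl.values[box.slice()][sel]
            assert np.nanmax(np.abs(vals - float(row["chl"].iloc[0]))) <= 1e-9

    def test_pla_recovered_within_rasterization_error(self):
        # larger rosettes (later time, finer pixels) keep the pixel-count
        # area within a few percent of the programmed area
        cfg = SimulationConfig(
            n_genotypes=2, n_replicates=6, seed=22, box_px=100, start_day=24,
            pla_residual_cv=0.0, movement_amplitude_pct=0.0,
        )
        _, truth = simulate_phenotypes(cfg, n_days=1)
        t0 = float(truth.phenotypes["time_h"].min())
        imgs = render_tile_images(truth, 0, t0)
        pixel_area = (truth.layout.plant_pitch_mm / cfg.box_px) ** 2
        grid = uniform_grid(imgs.nir.shape, (3, 4))
        for i, box in enumerate(boxes_from_grid(grid, imgs.nir.shape)):
            xw, yw = divmod(i, 4)
            row = imgs.true_values[
                (imgs.true_values.x_within == xw) & (imgs.true_values.y_within == yw)
            ]
            mask = threshold_mask(imgs.nir, box, "auto")
            area = projected_leaf_area(None, mask.mask, pixel_area)
            assert area.area_mm2 == pytest.approx(float(row["pla"].iloc[0]), rel=0.03)

    def test_zero_area_plant_gives_empty_mask(self):
        cfg = flat_config(initial_area_mm2=0.0, n_genotypes=2, n_replicates=6)
        _, truth = simulate_phenotypes(cfg, n_days=1)
        imgs = render_tile_images(truth, 0, float(truth.phenotypes["time_h"].min()))
        assert not imgs.true_mask.any()
        assert imgs.nir.max() == pytest.approx(truth.config.nir_background_level)

    def test_noisy_recovery_median_error_small(self, truth):
        t0 = self._phi_time(truth)
        imgs = render_tile_images(truth, 0, t0, rng=np.random.default_rng(3))
        corr = compute_target_factor(
            imgs.target_actinic, imgs.target_saturating, imgs.target_region
        )
        phi = compute_phipsii(
            average_frames(imgs.fs_stack),
            select_fm_prime(imgs.sat_stack),
            average_frames(imgs.dark_stack),
            corr,
        )
        errs = []
        for r in imgs.true_values.itertuples():
            box = uniform_grid(imgs.nir.shape, (3, 4))
            b = boxes_from_grid(box, imgs.nir.shape)[int(r.x_within) * 4 + int(r.y_within)]
            sel = imgs.true_mask[b.slice()]
            if sel.any():
                errs.extend(np.abs(phi.values[b.slice()][sel] - r.phipsii))
        assert np.median(errs) <= 0.01


class TestFixtures:
    def test_minimal_fixture_structure(self, tmp_path):
        manifest = make_fixture("minimal", tmp_path / "fx", seed=1)
        assert manifest["n_plants"] == 12
        assert len(manifest["phi_times"]) == 3
        assert manifest["mask_bearing_images_per_day"] == 11
        assert (tmp_path / "fx" / "genotype_map.csv").exists()
        assert len(manifest["images"]) == 3  # one tile, three efficiency times

    def test_unknown_scenario_lists_options(self, tmp_path):
        with pytest.raises(ValueError, match="minimal"):
            make_fixture("bogus", tmp_path)

    def test_same_seed_byte_identical_csvs(self, tmp_path):
        make_fixture("minimal", tmp_path / "a", seed=7, write_images=False)
        make_fixture("minimal", tmp_path / "b", seed=7, write_images=False)
        for rel in ("table.csv", "genotype_map.csv", "truth/phenotypes.csv"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_paperlike_counts(self, tmp_path):
        manifest = make_fixture("paperlike", tmp_path / "fx", seed=0, n_days=1)
        assert manifest["n_plants"] == 1440
        assert manifest["mask_bearing_images_per_day"] == 11
        table = pd.read_csv(tmp_path / "fx" / "table.csv")
        assert table.groupby("trait")["position"].nunique().max() == 1440

    def test_extremes_scenario_inflates_genotypic_variance(self, tmp_path):
        from phenopipe.quantgen import estimate_heritability

        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            res = {}
            for ext in (False, True):
                cfg = SimulationConfig(seed=seed, include_extremes=ext)
                table, _ = simulate_phenotypes(cfg, n_days=1, traits=("phipsii",))
                est = estimate_heritability(
                    table, trait="phipsii", time_h=table.time_h.min()
                )
                res[ext] = est.sigma2_G
            wins += res[True] > res[False]
        assert wins == n_seeds
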