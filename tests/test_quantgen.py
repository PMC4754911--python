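import numpy as np
import pandas as pd
import pytest

from conftest import make_oneway_table, oneway_anova_oracle
from phenopipe.layout import default_schedule
from phenopipe.quantgen import (
    compute_blues,
    estimate_heritability,
    fit_variance_components,
    heritability_timecourse,
    timecourse_frame,
)
from phenopipe.simulate import SimulationConfig, _default_variances, simulate_phenotypes


def variances(**overrides):
    v = _default_variances()
    for k in v["phipsii"]:
        v["phipsii"][k] = 0.0
    v["phipsii"].update(overrides)
    return v


class TestVarianceComponents:
    def test_reml_matches_balanced_anova_closed_form(self):
        df = make_oneway_table(5, 4, sigma_g=2.0, sigma_e=1.0, seed=0)
        vc = fit_variance_components(df, random_terms=["genotype"])
        s2g, s2e = oneway_anova_oracle(df, 4)
        assert vc["genotype"] == pytest.approx(s2g, abs=1e-6)
        assert vc["residual"] == pytest.approx(s2e, abs=1e-6)

    def test_zero_genotype_signal_gives_near_zero_component(self):
        df = make_oneway_table(10, 6, sigma_g=0.0, sigma_e=1.0, seed=3)
        vc = fit_variance_components(df, random_terms=["genotype"])
        assert vc["genotype"] < 0.3 * vc["residual"]

    def test_single_level_term_dropped_with_warning(self):
        df = make_oneway_table(4, 3, sigma_g=1.0, sigma_e=1.0)
        with pytest.warns(UserWarning, match="basin"):
            vc = fit_variance_components(df, random_terms=["genotype", "basin"])
        assert "basin" in vc.dropped_terms
        assert "basin" not in vc.components

    def test_parameter_recovery_over_seeds(self):
        # average REML estimates over seeds should track the generating values
        true_g, true_e = 6.25e-4, 6.25e-4
        ests_g, ests_e = [], []
        for seed in range(25):
            table, _ = simulate_phenotypes(
                SimulationConfig(
                    seed=seed,
                    variances=variances(genotype=true_g, residual=true_e),
                    phipsii_diel_amplitude=0.0,
                ),
                n_days=1,
                traits=("phipsii",),
            )
            vc = fit_variance_components(
                table, trait="phipsii", time_h=table.time_h.min(), random_terms=["genotype"]
            )
            ests_g.append(vc["genotype"])
            ests_e.append(vc["residual"])
        assert np.mean(ests_g) == pytest.approx(true_g, rel=0.25)
        assert np.mean(ests_e) == pytest.approx(true_e, rel=0.15)

    def test_experiment_terms_dropped_for_single_experiment(self):
        table, _ = simulate_phenotypes(
            SimulationConfig(seed=0), n_days=1, traits=("phipsii",)
        )
        vc = fit_variance_components(table, trait="phipsii", time_h=table.time_h.min())
        assert all("experiment" not in k for k in vc.components)

    def test_gxe_negligible_and_ranking_consistent_across_experiments(self):
        # with negligible genotype-by-experiment interaction, pooling two
        # experiments through the model recovers the true genotype ranking
        rhos = []
        for seed in (11, 12, 13):
            cfg = SimulationConfig(
                seed=seed, n_experiments=2, n_replicates=8, phipsii_diel_amplitude=0.0
            )
            table, truth = simulate_phenotypes(cfg, n_days=1, traits=("phipsii",))
            if seed == 11:
                vc = fit_variance_components(
                    table, trait="phipsii", time_h=table.time_h.min()
                )
                assert "genotype:experiment" in vc.components
                assert vc["genotype:experiment"] <= 0.5 * vc["genotype"]
            daily = [
                compute_blues(table, trait="phipsii", time_h=t)
                for t in sorted(table.time_h.unique())
            ]
            blues = pd.concat(daily, axis=1).mean(axis=1)
            eff = truth.genotype_effects.set_index("genotype")["phipsii_effect"]
            joined = pd.concat([blues, eff], axis=1, join="inner")
            rhos.append(joined.corr(method="spearman").iloc[0, 1])
        assert np.mean(rhos) >= 0.95
        assert min(rhos) >= 0.90


class TestBlues:
    def test_balanced_no_design_variance_equals_arithmetic_means(self):
        df = make_oneway_table(6, 4, sigma_g=1.5, sigma_e=0.5, seed=2)
        blues = compute_blues(df)
        means = df.groupby("genotype")["value"].mean()
        np.testing.assert_allclose(blues.values, means.values, atol=1e-8)

    def test_shift_equivariance(self):
        df = make_oneway_table(5, 4, sigma_g=1.0, sigma_e=1.0, seed=4)
        b0 = compute_blues(df)
        shifted = df.assign(value=df["value"] + 100.0)
        b1 = compute_blues(shifted)
        np.testing.assert_allclose(b1.values - b0.values, 100.0, atol=1e-6)

    def test_blues_beat_raw_means_under_spatial_gradient(self):
        # with a strong within-image gradient, the adjusted genotype means
        # should recover the true effects at least as well as raw means
        cfg = SimulationConfig(
            seed=9,
            n_replicates=8,
            variances=variances(genotype=6.25e-4, residual=3e-4, x_within=3e-3, y_within=3e-3),
            phipsii_diel_amplitude=0.0,
        )
        table, truth = simulate_phenotypes(cfg, n_days=1, traits=("phipsii",))
        t0 = table.time_h.min()
        sub = table[table.time_h == t0]
        blues = compute_blues(table, trait="phipsii", time_h=t0)
        raw = sub.groupby("genotype")["value"].mean()
        eff = truth.genotype_effects.set_index("genotype")["phipsii_effect"]
        r_blue = np.corrcoef(blues.reindex(eff.index), eff)[0, 1]
        r_raw = np.corrcoef(raw.reindex(eff.index), eff)[0, 1]
        assert r_blue >= r_raw - 0.02

    def test_checks_used_in_fit_but_absent_from_output(self):
        cfg = SimulationConfig(seed=1, n_check_genotypes=2)
        table, _ = simulate_phenotypes(cfg, n_days=1, traits=("phipsii",))
        blues = compute_blues(table, trait="phipsii", time_h=table.time_h.min())
        assert not any(g.startswith("CHK") for g in blues.index)


class TestHeritability:
    def test_formula_forced_values(self):
        # data engineered so MS_G = 10, MS_E = 2, r = 4, hence
        # sigma2_G = (10 - 2)/4 = 2 and H2 = 2/(2 + 2) = 0.5
        a = np.sqrt(1.5)  # within-genotype spread: SS_E = 8 a^2, df_E = 6
        d = np.sqrt(5.0)  # between-genotype spread: MS_G = 2 d^2
        df = make_oneway_table(2, 4, sigma_g=0.0, sigma_e=0.0)
        df["value"] = np.concatenate(
            [np.array([-a, a, -a, a]) - d / 2, np.array([-a, a, -a, a]) + d / 2]
        )
        est = estimate_heritability(df)
        assert est.MS_G == pytest.approx(10.0)
        assert est.MS_E == pytest.approx(2.0)
        assert est.r_bar == pytest.approx(4.0)
        assert est.sigma2_G == pytest.approx(2.0)
        assert est.H2 == pytest.approx(0.5)

    def test_truncation_when_msg_below_mse(self):
        df = make_oneway_table(8, 4, sigma_g=0.0, sigma_e=1.0, seed=11)
        est = estimate_heritability(df)
        if est.MS_G <= est.MS_E:
            assert est.H2 == 0.0
        assert 0.0 <= est.H2 <= 1.0

    def test_h2_bounds_and_ci_ordering(self):
        est = estimate_heritability(make_oneway_table(10, 4, 1.0, 1.0, seed=5))
        lo, hi = est.ci95
        assert 0.0 <= lo <= est.H2 + 1e-9 or lo <= hi
        assert 0.0 <= lo <= hi <= 1.0

    def test_scale_equivariance(self):
        df = make_oneway_table(6, 4, 1.0, 1.0, seed=6)
        e1 = estimate_heritability(df)
        e2 = estimate_heritability(df.assign(value=df["value"] * 10.0))
        assert e2.sigma2_G == pytest.approx(100 * e1.sigma2_G, rel=1e-6)
        assert e2.sigma2_E == pytest.approx(100 * e1.sigma2_E, rel=1e-6)
        assert e2.H2 == pytest.approx(e1.H2, abs=1e-10)

    def test_harmonic_mean_replicates_for_unbalanced_design(self):
        df = make_oneway_table(4, 4, 1.0, 1.0, seed=7)
        df = df.iloc[:-2]  # drop two replicates of the last genotype
        est = estimate_heritability(df)
        counts = df.groupby("genotype").size()
        expected = len(counts) / np.sum(1.0 / counts.to_numpy())
        assert est.r_bar == pytest.approx(expected)

    def test_bootstrap_ci_available(self):
        df = make_oneway_table(6, 4, 1.0, 1.0, seed=8)
        est = estimate_heritability(df, ci_method="bootstrap", n_boot=50)
        assert 0.0 <= est.ci95[0] <= est.ci95[1] <= 1.0


class TestTimecourse:
    def test_single_time_point_equals_direct_estimate(self):
        df = make_oneway_table(5, 4, 1.0, 1.0, seed=9)
        ests = heritability_timecourse(df, "trait")
        direct = estimate_heritability(df)
        assert len(ests) == 1
        assert ests[0].H2 == pytest.approx(direct.H2)

    def test_day_night_annotation(self):
        cfg = SimulationConfig(seed=0)
        table, _ = simulate_phenotypes(cfg, n_days=1, traits=("pla",))
        ests = heritability_timecourse(table, "pla", schedule=default_schedule())
        frame = timecourse_frame(ests)
        assert frame["is_day"].notna().all()
        assert set(frame.columns) >= {"trait", "time_h", "H2", "lo95", "hi95"}

    def test_programmed_diel_oscillation_recovered(self):
        errs, est, true = [], None, None
        for seed in range(4):
            cfg = SimulationConfig(
                seed=seed, n_replicates=24, genotype_modulation_amp=0.5,
                phipsii_diel_amplitude=0.0,
            )
            table, truth = simulate_phenotypes(cfg, n_days=2, traits=("phipsii",))
            ests = heritability_timecourse(table, "phipsii")
            est = np.array([e.H2 for e in ests])
            true = truth.timecourse["H2_realized"].to_numpy()
            errs.append(np.abs(est - true))
        assert np.mean(errs) <= 0.1
        # the estimated curve co-varies with the programmed one (peak at lag 0)
        assert np.corrcoef(est, true)[0, 1] > 0.8

    def test_excluding_extreme_genotypes_lowers_h2(self):
        cfg = SimulationConfig(seed=13, include_extremes=True)
        table, _ = simulate_phenotypes(cfg, n_days=1, traits=("phipsii",))
        t0 = table.time_h.min()
        with_ext = estimate_heritability(table, trait="phipsii", time_h=t0)
        normal = sorted(g for g in table.genotype.unique() if g.startswith("G"))
        without = estimate_heritability(table, trait="phipsii", time_h=t0, genotypes=normal)
        assert with_ext.H2 > without.H2

    def test_empty_genotype_subset_rejected(self):
        df = make_oneway_table(5, 4, 1.0, 1.0)
        with pytest.raises(ValueError):
            heritability_timecourse(df, "trait", genotypes=[])
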