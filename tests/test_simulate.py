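"""Synthetic cohort generator: determinism, marginals, programmed effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glucopheno.curves import CANONICAL_GRID
from glucopheno.features import extract_features
from glucopheno.indices import incretin_effect
from glucopheno.kinetics import parameters_for
from glucopheno.simulate import (
    LatentState,
    SimulationConfig,
    sample_covariates,
    sample_latent_state,
    simulate_cgm,
    simulate_cpeptide_pair,
    simulate_ogtt_glucose,
)


class TestCovariates:
    def test_seed_determinism(self):
        a = sample_covariates(200, seed=1)
        b = sample_covariates(200, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_extending_cohort_preserves_existing_participants(self):
        """Counter-based streams: the first rows of a larger cohort are
        identical to the smaller cohort."""
        small = sample_covariates(50, seed=4)
        large = sample_covariates(80, seed=4)
        pd.testing.assert_frame_equal(small, large.iloc[:50])

    def test_marginal_means_match_generator(self):
        """Monte-Carlo means against the analytic truncated-normal oracle
        (scipy.stats.truncnorm) for the stated marginals."""
        cov = sample_covariates(6000, seed=2)
        bmi_mean = stats.truncnorm.mean(
            (23 - 26) / 5, (40 - 26) / 5, loc=26, scale=5
        )
        assert cov["bmi"].mean() == pytest.approx(bmi_mean, abs=0.2)
        assert cov["age"].mean() == pytest.approx(55.0, abs=0.5)
        assert cov["fasting_insulin"].mean() == pytest.approx(10.0, rel=0.05)
        assert cov["sex"].mean() == pytest.approx(0.5, abs=0.03)
        assert cov["bmi"].between(23, 40).all()
        assert (cov["hdl"] > 20).all()

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            sample_covariates(0)


class TestLatentState:
    def test_default_correlations_recovered(self):
        cfg = SimulationConfig(n_participants=5000, seed=11)
        lat = sample_latent_state(sample_covariates(5000, 11), cfg)
        assert np.corrcoef(lat["sspg"], lat["hep_ir"])[0, 1] == pytest.approx(
            0.70, abs=0.03
        )
        Z = lat[["z_muscle", "z_beta", "z_incretin", "z_hepatic"]].to_numpy()
        C = np.corrcoef(Z.T)
        assert np.allclose(C, cfg.latent_correlations, atol=0.05)

    def test_identity_correlations_give_independence(self):
        cfg = SimulationConfig(
            n_participants=4000, seed=5,
            latent_correlations=np.eye(4), bmi_loading=0.0,
        )
        lat = sample_latent_state(sample_covariates(4000, 5), cfg)
        Z = lat[["z_muscle", "z_beta", "z_incretin", "z_hepatic"]].to_numpy()
        off = np.corrcoef(Z.T) - np.eye(4)
        assert np.abs(off).max() <= 0.05

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(n_participants=100, seed=9)
        cov = sample_covariates(100, 9)
        pd.testing.assert_frame_equal(
            sample_latent_state(cov, cfg), sample_latent_state(cov, cfg)
        )

    def test_non_psd_matrix_rejected(self):
        C = np.eye(4)
        C[0, 1] = C[1, 0] = 0.99
        C[0, 2] = C[2, 0] = 0.99
        C[1, 2] = C[2, 1] = -0.99
        with pytest.raises(ValueError):
            SimulationConfig(latent_correlations=C)

    def test_state_invariants(self):
        cfg = SimulationConfig(n_participants=500, seed=3)
        lat = sample_latent_state(sample_covariates(500, 3), cfg)
        assert lat["sspg"].between(40, 300).all()
        assert lat["ie_frac"].between(0, 1).all()
        assert (lat["beta_capacity"] > 0).all()


class TestGlucoseCurves:
    def _state(self, z_m=0.0, z_b=0.0, z_i=0.0, z_h=0.0):
        return pd.Series({
            "z_muscle": z_m, "z_beta": z_b, "z_incretin": z_i,
            "z_hepatic": z_h, "beta_capacity": np.exp(-0.5 * z_b),
            "ie_frac": 0.5,
        })

    def test_canonical_grid_output_has_16_points(self):
        g = simulate_ogtt_glucose(self._state(), seed=0)
        assert g.values.size == 16 and g.is_canonical

    def test_higher_muscle_ir_gives_larger_auc(self):
        """Noise-free curves at +/-2 SD of muscle IR: AUC strictly larger
        for the resistant state (direct evaluation of the kernel)."""
        cfg = SimulationConfig(plasma_noise_sd=0.0)
        hi = simulate_ogtt_glucose(self._state(z_m=2), seed=0, config=cfg)
        lo = simulate_ogtt_glucose(self._state(z_m=-2), seed=0, config=cfg)
        assert extract_features(hi)["AUC"] > extract_features(lo)["AUC"]

    def test_zero_effects_zero_noise_identical_curves(self):
        cfg = SimulationConfig(
            plasma_noise_sd=0.0,
            baseline_per_sd_hepatic=0, baseline_per_sd_muscle=0,
            peak_per_sd_muscle=0, peak_per_sd_incretin=0, peak_per_sd_beta=0,
            peak_time_per_sd_beta=0, peak_time_per_sd_muscle=0,
        )
        a = simulate_ogtt_glucose(self._state(z_m=2, z_b=-1), seed=0, config=cfg)
        b = simulate_ogtt_glucose(self._state(z_m=-2, z_b=1), seed=0, config=cfg)
        assert np.allclose(a.values, b.values)

    def test_grid_must_include_zero(self):
        with pytest.raises(ValueError):
            simulate_ogtt_glucose(self._state(), grid=np.array([10.0, 20.0]))

    def test_positive_values(self):
        g = simulate_ogtt_glucose(self._state(z_m=-3, z_b=-3), seed=0)
        assert (g.values > 0).all()


class TestCpeptidePair:
    def test_programmed_incretin_fraction_recovered(self, kinetic_params):
        """Forward/inverse consistency: ie_frac=0.5 without noise measures
        as a 50% incretin effect under trapezoid quadrature."""
        cfg = SimulationConfig(cpeptide_noise_cv=0.0, plasma_noise_sd=0.0)
        st_ = pd.Series({"z_muscle": 0.0, "z_beta": 0.0, "z_incretin": 0.0,
                         "z_hepatic": 0.0, "beta_capacity": 1.0,
                         "ie_frac": 0.5})
        g = simulate_ogtt_glucose(st_, seed=0, config=cfg)
        ogtt, iigi = simulate_cpeptide_pair(st_, g, kinetic_params, 0, cfg)
        assert incretin_effect(ogtt, iigi) == pytest.approx(50.0, abs=2.0)

    def test_zero_fraction_identical_series(self, kinetic_params):
        cfg = SimulationConfig(cpeptide_noise_cv=0.0, plasma_noise_sd=0.0)
        st_ = pd.Series({"z_muscle": 0.0, "z_beta": 0.0, "z_incretin": 0.0,
                         "z_hepatic": 0.0, "beta_capacity": 1.0,
                         "ie_frac": 0.0})
        g = simulate_ogtt_glucose(st_, seed=0, config=cfg)
        ogtt, iigi = simulate_cpeptide_pair(st_, g, kinetic_params, 0, cfg)
        assert np.allclose(ogtt.values, iigi.values)
        assert incretin_effect(ogtt, iigi) == pytest.approx(0.0, abs=1e-9)

    def test_reproducible_under_seed(self, kinetic_params):
        cfg = SimulationConfig()
        st_ = pd.Series({"z_muscle": 0.5, "z_beta": -0.2, "z_incretin": 0.1,
                         "z_hepatic": 0.3, "beta_capacity": 1.1,
                         "ie_frac": 0.4})
        g = simulate_ogtt_glucose(st_, seed=7, config=cfg)
        a = simulate_cpeptide_pair(st_, g, kinetic_params, 7, cfg)
        b = simulate_cpeptide_pair(st_, g, kinetic_params, 7, cfg)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_noncanonical_glucose_rejected(self, kinetic_params):
        from glucopheno.curves import GlucoseCurve

        g = GlucoseCurve("p", "plasma", "t", np.arange(0, 100, 10.0),
                         np.full(10, 100.0))
        with pytest.raises(ValueError):
            simulate_cpeptide_pair(LatentState(100, 1.0, 0.5, 0.0), g,
                                   kinetic_params)


class TestEffectDirections:
    def test_programmed_signs_recovered_at_cohort_scale(self):
        """Over >=1000 simulated participants the feature-phenotype signs
        must match the programmed physiology: AUC rises with SSPG, 2-h
        glucose falls with the disposition proxy, positive incremental
        area falls with the incretin fraction."""
        cfg = SimulationConfig(n_participants=1000, seed=21)
        cov = sample_covariates(1000, 21)
        lat = sample_latent_state(cov, cfg)
        feats = []
        for i, (pid, row) in enumerate(lat.iterrows()):
            g = simulate_ogtt_glucose(row, CANONICAL_GRID, cfg.seed, cfg, i, pid)
            f = extract_features(g)
            feats.append((f["AUC"], f["G_120"], f["pAUC"]))
        auc, g120, pauc = np.array(feats).T
        di_proxy = lat["beta_capacity"] / lat["sspg"]
        assert np.corrcoef(auc, lat["sspg"])[0, 1] > 0
        assert np.corrcoef(g120, di_proxy)[0, 1] < 0
        assert np.corrcoef(pauc, lat["ie_frac"])[0, 1] < 0


class TestCgmReplicates:
    def test_invalid_test_count_rejected(self):
        g = simulate_ogtt_glucose(
            pd.Series({"z_muscle": 0, "z_beta": 0, "z_incretin": 0,
                       "z_hepatic": 0, "beta_capacity": 1, "ie_frac": 0.5}),
            seed=0,
        )
        with pytest.raises(ValueError):
            simulate_cgm(g, 0)

    def test_fixed_seed_reproducible(self):
        st_ = pd.Series({"z_muscle": 0, "z_beta": 0, "z_incretin": 0,
                         "z_hepatic": 0, "beta_capacity": 1, "ie_frac": 0.5})
        g = simulate_ogtt_glucose(st_, seed=3)
        a = simulate_cgm(g, 2, seed=3)
        b = simulate_cgm(g, 2, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)
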