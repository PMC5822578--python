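"""Generator: calibration transcription, moment fidelity, attrition, I/O."""

import copy

import numpy as np
import pandas as pd
import pytest
import yaml

from hippolcs import (
    apply_attrition,
    default_calibration,
    generate_cohort,
    read_cohort_csv,
    write_cohort_csv,
)
from hippolcs.cohort import baseline_cognitive_composite

from conftest import null_config


class TestDefaultCalibration:
    def test_printed_values_transcribed(self, config):
        vol = config.biomarkers["volume"]
        assert vol.mean_w2 == 6429.53 and vol.sd_w2 == 861.22
        assert config.biomarkers["fa"].stability == 0.67
        assert config.biomarkers["md"].change_mean_sd == 1.02
        assert config.biomarkers["t1"].change_mean_sd == -1.47
        assert config.domain_change_mean_sd["working_memory"] == -0.21
        assert config.biomarkers["md"].path("bio_level_cog_change", "working_memory") == -0.281
        assert (config.n_wave2, config.n_wave3) == (655, 469)
        assert config.metadata["sources"]

    def test_identity_structural_matrix_is_valid(self):
        cfg = null_config()
        R = cfg.cognitive_correlation()
        # cognitive block fully decoupled except own-domain level-change (zeroed)
        assert np.allclose(R, np.eye(6))
        cfg.validate()

    def test_derived_change_scale_reproduces_stability_algebra(self, config):
        # corr(w2, w3) = (1 + cov)/sqrt(var_w3) must return the calibrated r
        for bio in config.biomarkers.values():
            v3 = 1 + bio.change_var + 2 * bio.level_change_cov
            assert np.isclose((1 + bio.level_change_cov) / np.sqrt(v3), bio.stability)
            assert bio.change_var > 0

    def test_invalid_configs_raise(self, config):
        bad = copy.deepcopy(config)
        bad.n_wave3 = bad.n_wave2 + 1
        with pytest.raises(ValueError, match="n_wave3"):
            bad.validate()
        bad = copy.deepcopy(config)
        bad.indicators["spatial_span"].sd_w2 = -1.0
        with pytest.raises(ValueError, match="positive"):
            bad.validate()
        bad = copy.deepcopy(config)
        # mutually impossible correlations -> non-positive-definite block
        bad.biomarkers["md"].paths["level_level"] = {
            "verbal_memory": 0.95, "working_memory": 0.95, "speed": 0.95,
        }
        bad.domain_level_corr["verbal_memory"]["working_memory"] = -0.9
        bad.domain_level_corr["working_memory"]["verbal_memory"] = -0.9
        with pytest.raises(ValueError, match="eigenvalue"):
            bad.validate()


class TestGenerateCohort:
    def test_wave2_biomarker_moments(self, cohort, config):
        vol = config.biomarkers["volume"]
        tol = 3 * vol.sd_w2 / np.sqrt(config.n_wave2)
        assert abs(cohort["volume_w2"].mean() - vol.mean_w2) < tol

    def test_table_invariants(self, cohort):
        assert cohort.index.is_unique
        assert ((cohort["fa_w2"] >= 0) & (cohort["fa_w2"] <= 1)).all()
        assert (cohort["volume_w2"] > 0).all()
        assert (cohort["age_days_test_w3"] > cohort["age_days_test_w2"]).all()

    def test_determinism_byte_identical(self, config):
        a = generate_cohort(config, seed=5)
        b = generate_cohort(config, seed=5)
        pd.testing.assert_frame_equal(a, b, check_exact=True)
        assert a.to_csv() == b.to_csv()

    def test_zero_noise_indicators_are_affine_in_latents(self, config):
        cfg = copy.deepcopy(config)
        cfg.zero_measurement_noise = True
        cfg.n_wave2, cfg.n_wave3 = 200, 150
        df = generate_cohort(cfg, seed=9)
        # same-domain indicators become perfectly correlated (up to sign)
        for a, b in [("logical_memory", "verbal_pairs"), ("digit_symbol", "choice_rt")]:
            r = np.corrcoef(df[f"{a}_w2"], df[f"{b}_w2"])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-12

    def test_fa_stability_monte_carlo(self, config):
        cfg = copy.deepcopy(config)
        cfg.n_wave2, cfg.n_wave3 = 10_000, 7_000
        df = generate_cohort(cfg, seed=1)
        r = np.corrcoef(df["fa_w2"], df["fa_w3"])[0, 1]
        assert abs(r - 0.67) < 0.02

    def test_structural_moments_converge(self, config):
        """Sample moments of the (noise-free) structural variables match the
        configured moments within Monte-Carlo error at n=20,000."""
        cfg = copy.deepcopy(config)
        cfg.zero_measurement_noise = True
        cfg.n_wave2, cfg.n_wave3 = 20_000, 14_000
        df = generate_cohort(cfg, seed=11)
        n = cfg.n_wave2
        bio = cfg.biomarkers["md"]
        lev = (df["md_w2"] - bio.mean_w2) / bio.sd_w2
        chg = (df["md_w3"] - df["md_w2"]) / bio.sd_w2
        lam = cfg.loading("spatial_span")
        tau = cfg.intercept("spatial_span")
        wm_lev = (df["spatial_span_w2"] - tau) / lam
        wm_chg = (df["spatial_span_w3"] - df["spatial_span_w2"]) / lam
        # means (4 MC SEs)
        assert abs(chg.mean() - bio.change_mean_sd) < 4 * bio.change_sd / np.sqrt(n)
        wm_sd = cfg.domain_change_sd["working_memory"]
        assert abs(wm_chg.mean() - (-0.21)) < 4 * wm_sd / np.sqrt(n)
        # correlations (4 * (1-r^2)/sqrt(n))
        checks = [
            (lev, chg, bio.level_change_cov / bio.change_sd),
            (lev, wm_chg, bio.path("bio_level_cog_change", "working_memory")),
            (lev, wm_lev, bio.path("level_level", "working_memory")),
            (chg, wm_chg, bio.path("change_change", "working_memory")),
        ]
        for x, y, r_true in checks:
            r = np.corrcoef(x, y)[0, 1]
            assert abs(r - r_true) < 4 * (1 - r_true**2) / np.sqrt(n)

    def test_wave3_equals_level_plus_change_exactly(self, config):
        cfg = copy.deepcopy(config)
        cfg.zero_measurement_noise = True
        cfg.n_wave2, cfg.n_wave3 = 300, 200
        df = generate_cohort(cfg, seed=3)
        # with zero residuals the marker difference *is* the latent change:
        # w3 - w2 = loading * change, reconstructed without approximation
        lam = cfg.loading("logical_memory")
        chg = (df["logical_memory_w3"] - df["logical_memory_w2"]) / lam
        vp_lam = cfg.loading("verbal_pairs")
        chg_vp = (df["verbal_pairs_w3"] - df["verbal_pairs_w2"]) / vp_lam
        assert np.allclose(chg, chg_vp, atol=1e-10)


class TestAttrition:
    def test_no_selection_is_random_thinning(self, config):
        cfg = copy.deepcopy(config)
        cfg.attrition_slope = 0.0
        table = generate_cohort(cfg, seed=21)
        out = apply_attrition(table, cfg, seed=22)
        p = cfg.n_wave3 / cfg.n_wave2
        se = np.sqrt(cfg.n_wave2 * p * (1 - p))
        kept = out["volume_w3"].notna().sum()
        assert abs(kept - cfg.n_wave3) < 3 * se

    def test_returners_have_higher_baseline_cognition(self, config):
        diffs = []
        for s in range(20):
            table = generate_cohort(config, seed=100 + s)
            out = apply_attrition(table, config, seed=200 + s)
            g = baseline_cognitive_composite(out, config)
            ret = out["volume_w3"].notna()
            diffs.append(g[ret].mean() - g[~ret].mean())
        diffs = np.array(diffs)
        assert (diffs > 0).all()
        assert diffs.mean() > 0.2

    def test_expected_retention_near_target(self, config, cohort):
        p = config.n_wave3 / config.n_wave2
        se = np.sqrt(config.n_wave2 * p * (1 - p))
        kept = apply_attrition(cohort, config, seed=77)["md_w3"].notna().sum()
        assert abs(kept - config.n_wave3) < 3 * se

    def test_wave2_untouched_and_wave3_fully_blanked(self, config, cohort, attrited):
        w2_cols = [c for c in cohort.columns if c.endswith("_w2")] + ["sex"]
        pd.testing.assert_frame_equal(cohort[w2_cols], attrited[w2_cols])
        gone = attrited["volume_w3"].isna()
        w3_meas = [
            c for c in cohort.columns if c.endswith("_w3") and not c.startswith("age")
        ]
        assert attrited.loc[gone, w3_meas].isna().all().all()


class TestIO:
    def test_csv_roundtrip_preserves_missingness(self, attrited, config, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(attrited, path, config, seed=42)
        back = read_cohort_csv(path)
        assert back.shape == attrited.shape
        pd.testing.assert_frame_equal(back, attrited, check_exact=False, rtol=1e-12)
        assert back["md_w3"].isna().equals(attrited["md_w3"].isna())
        sidecar = tmp_path / "cohort.config.yaml"
        payload = yaml.safe_load(sidecar.read_text())
        assert payload["seed"] == 42
        assert payload["generator"]["n_wave2"] == config.n_wave2
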