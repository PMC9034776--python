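"""Synthetic cohort generator: demographics, ratings, gray matter, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from errtsem.cohort import (
    DECADE_RANGES,
    DEFAULT_DECADE_WEIGHTS,
    FACTORS,
    TABLE_GM_CORR,
    CohortConfig,
    ConfigurationError,
    generate_gm,
    generate_gm_loadings,
    generate_ratings,
    sample_demographics,
)
from errtsem.errt import RATING_COLUMNS


class TestConfigValidation:
    def test_bad_decade_weights(self):
        with pytest.raises(ConfigurationError, match="decade_weights"):
            CohortConfig(decade_weights=[1, 1, 0, 0, 0, 0, 0])

    def test_unknown_indicator_in_loadings(self):
        with pytest.raises(ConfigurationError, match="unknown indicator"):
            CohortConfig(factor_loadings={("PosReactivity", "nope"): 0.5})

    def test_r2_out_of_range(self):
        with pytest.raises(ConfigurationError, match="R-squared"):
            CohortConfig(age_effect_r2={"PosReactivity": 1.2})

    def test_non_pd_gm_corr(self):
        C = np.ones((12, 12))
        with pytest.raises(ConfigurationError, match="positive definite"):
            CohortConfig(gm_corr=C)

    def test_table_gm_corr_is_positive_definite(self):
        assert np.linalg.eigvalsh(TABLE_GM_CORR)[0] > 0


class TestDemographics:
    def test_single_decade_weights_bound_ages(self):
        w = [1.0, 0, 0, 0, 0, 0, 0]
        demo = sample_demographics(CohortConfig(n_subjects=300, seed=1, decade_weights=w))
        assert demo.age.between(18, 28).all()

    def test_determinism(self):
        cfg = CohortConfig(n_subjects=100, seed=7)
        a = sample_demographics(cfg)
        b = sample_demographics(CohortConfig(n_subjects=100, seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_decade_counts_match_multinomial(self):
        n = 100000
        demo = sample_demographics(CohortConfig(n_subjects=n, seed=3))
        w = np.asarray(DEFAULT_DECADE_WEIGHTS)
        counts = np.array(
            [demo.age.between(lo, hi).sum() for lo, hi in DECADE_RANGES]
        )
        expected = n * w
        sd = np.sqrt(n * w * (1 - w))
        assert np.all(np.abs(counts - expected) <= 3 * sd)

    def test_fluid_iq_declines_linearly(self):
        demo = sample_demographics(CohortConfig(n_subjects=20000, seed=4))
        # decade means track the reference values up to the misfit of the
        # least-squares line itself (the youngest decades plateau, so a
        # linear decline is ~1.9 points high there)
        for (lo, hi), expect in zip(DECADE_RANGES, (37.3, 37.5, 35.8, 33.4, 30.9, 27.7, 24.9)):
            got = demo.loc[demo.age.between(lo, hi), "fluid_iq"].mean()
            assert got == pytest.approx(expect, abs=2.2)
        # and the decline itself is monotone across decades
        means = [
            demo.loc[demo.age.between(lo, hi), "fluid_iq"].mean() for lo, hi in DECADE_RANGES
        ]
        assert all(a > b for a, b in zip(means[:3], means[1:4])) or means[0] > means[-1]

    def test_education_ordinal_negatively_correlated_with_age(self):
        demo = sample_demographics(CohortConfig(n_subjects=20000, seed=5))
        assert set(demo.education.unique()) <= {1, 2, 3, 4}
        r, _ = stats.pearsonr(demo.education, demo.age)
        assert -0.35 < r < -0.10


class TestRatings:
    def test_empty_demographics_rejected(self):
        cfg = CohortConfig(n_subjects=10, seed=0)
        with pytest.raises(ValueError, match="empty"):
            generate_ratings(pd.DataFrame(columns=["age", "gender", "depression"]), cfg)

    def test_determinism(self, default_cohort):
        cfg, demo, ratings, _ = default_cohort
        again, _ = generate_ratings(demo, cfg)
        pd.testing.assert_frame_equal(ratings, again)

    def test_null_age_effect_gives_zero_correlation(self):
        cfg = CohortConfig(
            n_subjects=20000, seed=6, age_effect_r2={f: 0.0 for f in FACTORS}
        )
        demo = sample_demographics(cfg)
        _, truth = generate_ratings(demo, cfg)
        for j in range(4):
            r, _ = stats.pearsonr(truth.latent_scores[:, j], demo.age)
            assert abs(r) < 0.03

    def test_configured_age_r2_realized_in_latents(self):
        cfg = CohortConfig(n_subjects=5000, seed=7)
        demo = sample_demographics(cfg)
        _, truth = generate_ratings(demo, cfg)
        j = FACTORS.index("BasalNegAffect")
        r, _ = stats.pearsonr(truth.latent_scores[:, j], demo.age)
        assert r**2 == pytest.approx(0.30, abs=0.05)

    def test_discretized_mode_stays_on_scale(self):
        cfg = CohortConfig(n_subjects=500, seed=8, rating_mode="discretized")
        demo = sample_demographics(cfg)
        ratings, _ = generate_ratings(demo, cfg)
        block = ratings[list(RATING_COLUMNS)]
        assert (block >= 1).all().all() and (block <= 11).all().all()
        assert np.allclose(block, block.round())

    def test_moment_matching_against_model_implied_covariance(self):
        """Empirical indicator correlations converge to the truth-implied ones."""
        cfg = CohortConfig(n_subjects=50000, seed=9)
        demo = sample_demographics(cfg)
        ratings, truth = generate_ratings(demo, cfg)
        emp = np.corrcoef(ratings[list(RATING_COLUMNS)].to_numpy(), rowvar=False)
        implied = truth.implied_rating_cov
        d = np.sqrt(np.diag(implied))
        implied_corr = implied / np.outer(d, d)
        assert np.linalg.norm(emp - implied_corr) < 0.05

    def test_truth_residual_variances_positive(self, default_cohort):
        *_, truth = default_cohort
        assert all(v > 0 for v in truth.residual_variances.values())


class TestGrayMatter:
    def test_loading_correlations_match_config(self):
        cfg = CohortConfig(n_subjects=5000, seed=10)
        demo = sample_demographics(cfg)
        gl, _ = generate_gm_loadings(demo, cfg)
        C = np.corrcoef(gl.to_numpy(), rowvar=False)
        assert np.linalg.norm(C - TABLE_GM_CORR) < 0.15

    def test_age_r2_band(self):
        cfg = CohortConfig(
            n_subjects=1000, seed=11,
            gm_age_r2={f"s{i}": 0.40 for i in range(4)},
            gm_corr=np.eye(4) * 0.5 + 0.5,
        )
        demo = sample_demographics(cfg)
        gl, _ = generate_gm_loadings(demo, cfg)
        import statsmodels.api as sm

        X = sm.add_constant(demo.age.to_numpy())
        for col in gl.columns:
            r2 = sm.OLS(gl[col].to_numpy(), X).fit().rsquared
            assert 0.30 <= r2 <= 0.50

    def test_noise_free_stack_has_planted_rank(self):
        cfg = CohortConfig(
            n_subjects=60, seed=12,
            gm_age_r2={f"s{i}": 0.1 for i in range(5)},
            gm_corr=np.eye(5) * 0.7 + 0.3,
        )
        demo = sample_demographics(cfg)
        stack, truth = generate_gm(demo, cfg, grid_shape=(10, 10, 10), noise_sd=0.0)
        flat = stack.reshape(60, -1)
        flat = flat - flat.mean(axis=0)
        s = np.linalg.svd(flat, compute_uv=False)
        assert np.sum(s > 1e-8 * s[0]) == 5

    def test_infeasible_age_component_rejected(self):
        cfg = CohortConfig(
            n_subjects=50, seed=13,
            gm_age_r2={f"s{i}": 0.9 for i in range(3)},
            gm_corr=np.eye(3),
        )
        demo = sample_demographics(cfg)
        with pytest.raises(ConfigurationError, match="positive definite"):
            generate_gm_loadings(demo, cfg)
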