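"""Profile goodness of fit, normality/distribution tests, outcome rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fddflow.stats import (ClassifierConfig, Outcome, PoiseuilleSpec,
                           classify_outcome, ks_two_sample,
                           pearson_profile_pvalue, poiseuille_profile,
                           shapiro_wilk)


class TestPoiseuilleProfile:
    def test_wall_velocity_is_zero(self):
        spec = PoiseuilleSpec(P1=100.0, P2=0.0, L=0.02, eta=0.004, R=0.002)
        assert poiseuille_profile(spec.R, spec) == 0.0

    def test_centerline_maximum(self):
        spec = PoiseuilleSpec(P1=100.0, P2=0.0, L=0.02, eta=0.004, R=0.002)
        v0 = poiseuille_profile(0.0, spec)
        assert v0 == pytest.approx(100.0 * 0.002 ** 2 / (4 * 0.02 * 0.004))

    def test_hand_evaluated_point(self):
        spec = PoiseuilleSpec(P1=100.0, P2=0.0, L=0.02, eta=0.004, R=0.002)
        assert poiseuille_profile(0.001, spec) == pytest.approx(0.9375)

    def test_outside_radius_rejected(self):
        spec = PoiseuilleSpec(P1=1.0, P2=0.0, L=1.0, eta=1.0, R=1.0)
        with pytest.raises(ValueError):
            poiseuille_profile(1.5, spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PoiseuilleSpec(P1=0.0, P2=1.0, L=1.0, eta=1.0, R=1.0)


class TestPearson:
    def test_identical_profiles(self):
        v = np.linspace(0.01, 0.12, 40)
        chi2, p, dof = pearson_profile_pvalue(v, v)
        assert chi2 == 0.0 and p == 1.0 and dof == 39

    def test_chi2_at_its_mean(self):
        # chi2 = dof lands near the distribution centre: p ~ 0.46 at 60 dof
        p = float(sps.chi2.sf(60.0, 60))
        assert p == pytest.approx(0.46, abs=0.02)

    def test_wall_station_excluded(self):
        e = np.array([0.0, 0.1, 0.2])
        v = np.array([0.05, 0.1, 0.2])  # wall disagreement must not count
        chi2, p, dof = pearson_profile_pvalue(v, e)
        assert chi2 == 0.0 and dof == 1

    def test_monotone_in_perturbation(self):
        e = np.linspace(0.01, 0.12, 30)
        rng = np.random.default_rng(7)
        noise = rng.normal(0, 1, 30)
        chis = []
        for amp in (1e-4, 1e-3, 1e-2):
            c, _, _ = pearson_profile_pvalue(e + amp * noise, e)
            chis.append(c)
        assert chis[0] < chis[1] < chis[2]
        _, p_clean, _ = pearson_profile_pvalue(e, e)
        _, p_noisy, _ = pearson_profile_pvalue(e + 0.05 * np.abs(noise), e)
        assert p_noisy < p_clean

    def test_negative_expected_rejected(self):
        with pytest.raises(ValueError):
            pearson_profile_pvalue(np.array([0.1, 0.1]),
                                   np.array([0.1, -0.1]))

    def test_normalized_variant_is_scale_free(self):
        e = np.linspace(0.01, 0.12, 30)
        v = e * 1.01
        c1, _, _ = pearson_profile_pvalue(v, e, normalize=True)
        c2, _, _ = pearson_profile_pvalue(v * 1000, e * 1000,
                                          normalize=True)
        assert c1 == pytest.approx(c2, rel=1e-12)


class TestDistributionTests:
    def test_ks_identical_samples(self):
        x = np.linspace(0, 1, 50)
        stat, p = ks_two_sample(x, x)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_shapiro_type_one_error_rate(self):
        """On truly Gaussian draws the test rejects ~5% at alpha=0.05."""
        rng = np.random.default_rng(12345)
        rejections = sum(
            shapiro_wilk(rng.normal(size=5000))[1] < 0.05
            for _ in range(200))
        assert 2 <= rejections <= 22  # binomial(200, .05): central range

    def test_ks_detects_large_shift(self):
        rng = np.random.default_rng(99)
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(3.0, 1.0, 200)
        _, p = ks_two_sample(a, b)
        assert p < 0.01

    def test_shapiro_rejects_bimodal(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-3, 0.3, 300),
                            rng.normal(3, 0.3, 300)])
        _, p = shapiro_wilk(x)
        assert p < 0.01

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestClassifier:
    @pytest.mark.parametrize("series,expected", [
        ((19.02, 26.93, 26.62, 20.01), Outcome.STENOSIS),
        ((1.421, 1.918, 1.899, 1.491), Outcome.STENOSIS),
        ((1.141, 1.677, 1.660, 1.226), Outcome.NORM),
        ((0.997, 1.432, 1.426, 1.067), Outcome.NO_OCCLUSION),
    ])
    def test_reference_series_labels(self, series, expected):
        assert classify_outcome(series) is expected

    def test_mapping_input(self):
        s = {"t1": 19.02, "t2": 26.93, "t3": 26.62, "t4": 20.01}
        assert classify_outcome(s) is Outcome.STENOSIS

    def test_rounding_happens_before_comparison(self):
        # 1.6751 rounds to 1.68, so "max < 1.68" fails -> NORM
        assert classify_outcome((1.2, 1.6751, 1.5, 1.4)) is Outcome.NORM
        # 1.6749 rounds to 1.67 -> NO_OCCLUSION
        assert classify_outcome((1.2, 1.6749, 1.5, 1.4)) is \
            Outcome.NO_OCCLUSION

    @given(st.floats(1.0, 100.0))
    @settings(deadline=None)
    def test_scaling_a_stenosis_series_up_stays_stenosis(self, factor):
        base = np.array([1.421, 1.918, 1.899, 1.491])
        assert classify_outcome(base * factor) is Outcome.STENOSIS

    def test_missing_or_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            classify_outcome((1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            classify_outcome((1.0, 2.0, np.nan, 3.0))
        with pytest.raises(ValueError):
            classify_outcome({"t1": 1.0, "t2": 2.0})

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ClassifierConfig(theta_stenosis=2.0, theta_occlusion=1.0)
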