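"""Model-evaluation diagnostics: OLS oracles, Bland-Altman hand arithmetic,
rank-based NPDE behaviour, and VPC band structure."""

import numpy as np
import pytest

from pippk import (
    DiscreteDistribution,
    ErrorModel,
    PredictionRecord,
    bias_imprecision,
    bland_altman,
    gof_regression,
    npde_from_replicates,
    vpc,
)
from pippk.validation import mpe, prediction_errors


def _records(obs, pred):
    return [
        PredictionRecord("S", float(i), float(o), float(p), float(p))
        for i, (o, p) in enumerate(zip(obs, pred))
    ]


class TestGofRegression:
    def test_identity_line(self):
        r = gof_regression(_records([1, 2, 3, 4], [1, 2, 3, 4]))
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.r2 == pytest.approx(1.0)

    def test_pure_scaling(self):
        r = gof_regression(_records([2, 4, 6], [1, 2, 3]))
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)

    def test_toy_set_matches_closed_form_ols(self):
        # OLS of y = {1.1, 1.9, 3.2} on x = {1, 2, 3}:
        # slope = Sxy/Sxx = 2.1/2 = 1.05, intercept = ybar - slope*xbar
        r = gof_regression(_records([1.1, 1.9, 3.2], [1, 2, 3]))
        assert r.slope == pytest.approx(1.05, rel=1e-12)
        assert r.intercept == pytest.approx(2.0667 - 1.05 * 2.0, abs=1e-3)

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gof_regression(_records([1, 2, 3], [2, 2, 2]))


class TestBlandAltman:
    def test_perfect_agreement(self):
        r = bland_altman([(10.0, 10.0), (20.0, 20.0)])
        assert r.bias == r.upper_loa == r.lower_loa == 0.0

    def test_percent_mode_hand_arithmetic(self):
        # pairs (10,8), (8,10): differences +-2/9*100 = +-22.22%;
        # sample SD = 31.43, LoA = 0 +- 1.96*31.43 = +-61.60
        r = bland_altman([(10.0, 8.0), (8.0, 10.0)], scale="percent_of_mean")
        np.testing.assert_allclose(
            sorted(r.differences), [-22.2222, 22.2222], rtol=1e-4
        )
        assert r.bias == pytest.approx(0.0, abs=1e-12)
        assert r.upper_loa == pytest.approx(61.60, abs=0.01)
        assert r.lower_loa == pytest.approx(-61.60, abs=0.01)

    def test_absolute_mode_zero_variance(self):
        r = bland_altman([(2.0, 1.0), (3.0, 2.0), (4.0, 3.0)], scale="absolute")
        assert r.bias == pytest.approx(1.0)
        assert r.upper_loa == pytest.approx(1.0)
        assert r.lower_loa == pytest.approx(1.0)

    def test_zero_mean_pair_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            r = bland_altman([(1.0, -1.0), (10.0, 8.0), (8.0, 10.0)])
        assert r.n_excluded == 1

    def test_absolute_bias_equals_mpe(self):
        """Cross-module consistency: Bland-Altman absolute bias is the mean
        prediction error with the same observed-minus-predicted sign."""
        obs, pred = [12.0, 7.0, 30.0], [10.0, 9.0, 28.0]
        ba = bland_altman(list(zip(obs, pred)), scale="absolute")
        m, _ = mpe(prediction_errors(_records(obs, pred), "individual"))
        assert ba.bias == pytest.approx(m, rel=1e-12)


class TestBiasImprecision:
    def test_exact_predictions(self, error_model):
        b, i = bias_imprecision(_records([10, 20], [10, 20]), "population", error_model)
        assert b == 0.0 and i == 0.0

    def test_hand_weighted_errors(self):
        # constant SD 5: obs-pred = {+5, -5} -> weighted errors {+1, -1}
        em = ErrorModel(c0=5.0, c1=0.0, gamma=1.0)
        b, i = bias_imprecision(_records([15, 5], [10, 10]), "population", em)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert i == pytest.approx(2.0)  # sample variance of {1, -1}

    def test_constant_weighted_error(self):
        em = ErrorModel(c0=5.0, c1=0.0, gamma=1.0)
        b, i = bias_imprecision(_records([15, 25], [10, 20]), "population", em)
        assert b == pytest.approx(1.0)
        assert i == pytest.approx(0.0, abs=1e-12)


class TestNpdeValues:
    def test_boundary_below_all_simulations(self):
        from scipy.stats import norm

        sims = np.arange(1.0, 501.0)[None, :]  # 500 replicates
        v = npde_from_replicates(np.array([0.0]), sims)
        assert v[0] == pytest.approx(norm.ppf(1.0 / 1000.0))

    def test_monotone_in_observation(self):
        rng = np.random.default_rng(0)
        sims = rng.normal(size=(1, 600))
        obs_grid = np.linspace(-3, 3, 13)
        vals = [npde_from_replicates(np.array([o]), sims)[0] for o in obs_grid]
        assert np.all(np.diff(vals) >= 0)

    def test_invariant_under_joint_monotone_transform(self):
        rng = np.random.default_rng(1)
        sims = rng.lognormal(size=(5, 600))
        obs = rng.lognormal(size=5)
        a = npde_from_replicates(obs, sims)
        b = npde_from_replicates(np.log(obs), np.log(sims))
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestVpc:
    def test_bands_nested_everywhere(self, fitted, error_model):
        subjects, _, fit = fitted
        v = vpc(subjects, fit.distribution, error_model, n_sim=300, seed=1)
        assert np.all(v.q05 <= v.q50 + 1e-12)
        assert np.all(v.q50 <= v.q95 + 1e-12)
        assert 0.0 <= v.coverage <= 1.0

    def test_degenerate_population_band_collapses(self):
        """Single support point, no residual noise, homogeneous design:
        the predictive band is a single curve."""
        from pippk import DoseEvent, Regimen, SubjectRecord
        from pippk.covariates import PatientCovariates

        reg = Regimen(4000.0, 8.0, 0.5)
        subjects = [
            SubjectRecord(
                f"D{i}",
                [DoseEvent(0.0, 4000.0, 0.5)],
                np.array([1.0, 3.0]),
                np.array([50.0, 30.0]),
                covariates=PatientCovariates(
                    age=50, weight=70, height=170, sex="male", crcl=60.0
                ),
                steady_state=True,
                regimen=reg,
            )
            for i in range(3)
        ]
        point = DiscreteDistribution(
            ("tvcl", "v", "kcp", "kpc"), [[3.33, 10.69, 1.15, 0.08]], [1.0]
        )
        em = ErrorModel(c0=1.0, c1=0.1, gamma=1e-9)
        v = vpc(subjects, point, em, n_sim=200, seed=0)
        np.testing.assert_allclose(v.q05, v.q95, atol=1e-5)

    def test_requires_minimum_simulations(self, fitted, error_model):
        subjects, _, fit = fitted
        with pytest.raises(ValueError):
            vpc(subjects, fit.distribution, error_model, n_sim=50)
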