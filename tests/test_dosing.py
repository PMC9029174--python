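"""Monte Carlo dosing simulation: fT>MIC crossing oracles, population
sampling moments, PTA monotonicity/determinism, and FTA arithmetic."""

import numpy as np
import pytest

from pippk import (
    ConcentrationProfile,
    MICDistribution,
    PDTarget,
    PKParameters,
    Regimen,
    ft_above_mic,
    fta,
    lognormal_from_moments,
    pta,
    sample_population,
    steady_state_interval,
    synthetic_eucast_like_pa,
)


class TestSamplePopulation:
    def test_moments_mode_matches_targets(self):
        """1e5 log-normal draws reproduce the requested mean within 1% and
        SD within 2% (law of large numbers)."""
        draws = sample_population({"tvcl": (3.33, 1.24), "v": (10.69, 4.50)}, 100_000, crcl=60.0, seed=7)
        assert draws["tvcl"].mean() == pytest.approx(3.33, rel=0.01)
        assert draws["tvcl"].std() == pytest.approx(1.24, rel=0.02)
        assert draws["v"].mean() == pytest.approx(10.69, rel=0.01)

    def test_degenerate_single_point(self):
        from pippk import DiscreteDistribution

        d = DiscreteDistribution(("tvcl", "v"), [[3.0, 10.0]], [1.0])
        draws = sample_population(d, 50, crcl=60.0, seed=0)
        assert np.all(draws["tvcl"] == 3.0)
        assert np.all(draws["cl"] == 3.0)

    def test_crcl_scales_clearance_linearly(self):
        a = sample_population(None, 200, crcl=60.0, seed=3)
        b = sample_population(None, 200, crcl=120.0, seed=3)
        np.testing.assert_allclose(b["cl"], 2 * a["cl"], rtol=1e-12)

    def test_lognormal_moment_match_formula(self):
        mu, sigma = lognormal_from_moments(3.33, 1.24)
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(3.33, rel=1e-12)
        var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
        assert np.sqrt(var) == pytest.approx(1.24, rel=1e-12)


class TestFtAboveMic:
    def test_zero_mic_whole_interval(self):
        prof = steady_state_interval(PKParameters(3.33, 10.69, 1.15, 0.08), Regimen(4000, 8, 0.5))
        assert ft_above_mic(prof, 0.0) == 1.0

    def test_constant_level_equal_to_mic_is_not_above(self):
        # strict inequality: free concentration exactly at MIC counts as below
        prof = ConcentrationProfile(np.linspace(0, 6, 61), np.full(61, 10.0))
        assert ft_above_mic(prof, mic=7.0, fu=0.7) == 0.0

    def test_mono_exponential_hand_solve(self):
        """Free concentration 56 e^{-0.5 t} over 6 h, MIC 7: crossing at
        ln(8)/0.5 = 4.159 h, fraction 0.6931."""
        t = np.linspace(0, 6, 1201)
        total = (56.0 / 0.7) * np.exp(-0.5 * t)  # fu*total = 56 e^{-0.5t}
        prof = ConcentrationProfile(t, total, breakpoints=(0.0, 6.0))
        frac = ft_above_mic(prof, mic=7.0, fu=0.7)
        assert frac == pytest.approx(np.log(8.0) / 0.5 / 6.0, abs=5e-4)
        assert frac == pytest.approx(0.6931, abs=5e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_fine_grid_oracle(self, seed):
        """Bisection-located crossings vs a 1e-4 h brute-force grid."""
        r = np.random.default_rng(seed)
        p = PKParameters(r.uniform(1, 8), r.uniform(5, 25), r.uniform(0.5, 1.6), r.uniform(0.01, 0.3))
        reg = Regimen(4000.0, 6.0, 0.5)
        prof = steady_state_interval(p, reg)
        mic = float(r.choice([4.0, 16.0, 32.0, 64.0, 128.0]))
        got = ft_above_mic(prof, mic)
        grid = np.arange(0.0, reg.interval + 1e-12, 1e-4)
        oracle = np.mean(0.70 * prof.conc_at(grid) > mic)
        assert abs(got - oracle) < 1e-3


class TestPta:
    def test_pta_one_when_troughs_dominate_grid(self):
        res = pta(None, Regimen(4000, 6, 0.5), crcl=60.0, mic_grid=[0.0625, 0.125], n_sim=200, seed=0)
        np.testing.assert_allclose(res.pta, 1.0)

    def test_monotone_nonincreasing_in_mic(self):
        res = pta(None, Regimen(4000, 8, 0.5), crcl=90.0, n_sim=300, seed=4)
        assert np.all(np.diff(res.pta) <= 1e-12)

    def test_seed_determinism_bitwise(self):
        a = pta(None, Regimen(4000, 6, 0.5), crcl=60.0, n_sim=200, seed=11)
        b = pta(None, Regimen(4000, 6, 0.5), crcl=60.0, n_sim=200, seed=11)
        assert np.array_equal(a.pta, b.pta)

    def test_hundred_percent_target_never_easier(self):
        r50 = pta(None, Regimen(4000, 6, 0.5), 90.0, PDTarget(0.5), n_sim=300, seed=2)
        r100 = pta(None, Regimen(4000, 6, 0.5), 90.0, PDTarget(1.0), n_sim=300, seed=2)
        assert np.all(r100.pta <= r50.pta + 1e-12)


class TestFta:
    @staticmethod
    def _pta_result(mics, values):
        return pta.__wrapped__ if False else _FakePta(mics, values)

    def test_hand_weighted_average(self):
        fake = _FakePta([1.0, 8.0, 16.0], [1.0, 0.5, 0.0])
        dist = MICDistribution([1.0, 8.0, 16.0], [50, 30, 20], breakpoint=16.0)
        res = fta(fake, dist)
        assert res.fta_percent == pytest.approx(65.0)
        assert not res.optimal

    def test_perfect_pta_is_optimal(self):
        fake = _FakePta([1.0, 8.0], [1.0, 1.0])
        res = fta(fake, MICDistribution([1.0, 8.0], [10, 10], breakpoint=16.0))
        assert res.fta_percent == pytest.approx(100.0)
        assert res.optimal

    def test_entries_above_breakpoint_excluded(self):
        fake = _FakePta([1.0, 8.0, 16.0, 32.0], [1.0, 0.5, 0.0, 0.0])
        base = fta(fake, MICDistribution([1.0, 8.0, 16.0], [50, 30, 20], breakpoint=16.0))
        extended = fta(
            fake, MICDistribution([1.0, 8.0, 16.0, 32.0], [50, 30, 20, 1000], breakpoint=16.0)
        )
        assert extended.fta_percent == pytest.approx(base.fta_percent)

    def test_missing_pta_reported(self):
        fake = _FakePta([1.0, 8.0], [1.0, 0.5])
        with pytest.raises(ValueError, match="16"):
            fta(fake, MICDistribution([1.0, 8.0, 16.0], [5, 5, 5], breakpoint=16.0))


class _FakePta:
    """Minimal stand-in carrying a PTA grid (synthetic test helper)."""

    def __init__(self, mics, values):
        self.mic_grid = np.asarray(mics, dtype=float)
        self.pta = np.asarray(values, dtype=float)
        self.regimen = Regimen(4000.0, 6.0, 0.5)
        self.crcl = 60.0
        self.target = PDTarget(0.5)


class TestMicDistribution:
    def test_csv_round_trip(self, tmp_path):
        d = synthetic_eucast_like_pa()
        path = tmp_path / "mic.csv"
        d.to_csv(path)
        back = MICDistribution.from_csv(path)
        np.testing.assert_allclose(back.mics, d.mics)
        np.testing.assert_allclose(back.counts, d.counts)

    def test_validation(self):
        with pytest.raises(ValueError):
            MICDistribution([2.0, 1.0], [1, 1])  # not increasing
        with pytest.raises(ValueError):
            MICDistribution([1.0, 2.0], [1, -1])  # negative count
        with pytest.raises(ValueError):
            MICDistribution([4.0, 8.0], [1, 1], breakpoint=2.0)  # below grid
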