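import math

import numpy as np
import pytest

from palaeokit import radiocarbon as c14
from palaeokit import simulate as sim


class TestF14CConversion:
    def test_modern_standard_is_zero_bp(self):
        age = c14.f14c_to_age(c14.F14CMeasurement(1.0, 0.001))
        assert age.age_bp == pytest.approx(0.0)

    def test_half_modern(self):
        age = c14.f14c_to_age(c14.F14CMeasurement(0.5, 0.005))
        assert age.age_bp == pytest.approx(-8033 * math.log(0.5))
        assert age.sigma == pytest.approx(8033 * 0.005 / 0.5)

    def test_round_trip(self):
        for bp in (100.0, 5000.0, 30000.0):
            assert -8033 * math.log(c14.age_to_f14c(bp)) == pytest.approx(bp, abs=1e-9)

    def test_nonpositive_f14c_rejected(self):
        with pytest.raises(c14.ValidationError):
            c14.f14c_to_age(c14.F14CMeasurement(0.0, 0.001))


class TestBlankCorrect:
    def test_zero_blank_leaves_value(self):
        m = c14.F14CMeasurement(0.05, 0.001)
        out = c14.blank_correct(m, c14.F14CMeasurement(1e-12, 1e-13))
        assert out.f14c == pytest.approx(0.05, rel=1e-6)
        # quadrature term still inflates the error
        assert out.sigma_f > m.sigma_f

    def test_error_propagation_term_by_term(self):
        fm, fb, sm = 0.05, 0.005, 0.001
        out = c14.blank_correct(
            c14.F14CMeasurement(fm, sm), c14.F14CMeasurement(fb, 1e-6)
        )
        fc = (fm - fb) / (1 - fb)
        assert out.f14c == pytest.approx(fc)
        assert fc == pytest.approx(0.04523, abs=5e-6)
        sb = 0.30 * fb
        var = (sm / (1 - fb)) ** 2 + ((fm - 1) / (1 - fb) ** 2 * sb) ** 2
        var += (0.0016 * fc) ** 2
        assert out.sigma_f == pytest.approx(math.sqrt(var))

    def test_gas_uncertainty_larger_than_graphite(self):
        m_gr = c14.F14CMeasurement(0.05, 0.001, source="graphite")
        m_gas = c14.F14CMeasurement(0.05, 0.001, source="gas")
        blank = c14.F14CMeasurement(0.005, 1e-6)
        assert c14.blank_correct(m_gas, blank).sigma_f > c14.blank_correct(m_gr, blank).sigma_f

    def test_corrected_error_exceeds_naive_subtraction(self):
        m = c14.F14CMeasurement(0.05, 0.001)
        out = c14.blank_correct(m, c14.F14CMeasurement(0.005, 1e-6),
                                extra_rel_uncertainty=0.0)
        assert out.sigma_f >= m.sigma_f / (1 - 0.005) - 1e-15

    def test_below_background_flagged(self):
        out = c14.blank_correct(
            c14.F14CMeasurement(0.0001, 0.0001), c14.F14CMeasurement(0.005, 1e-6)
        )
        assert out.below_background


class TestCombineReplicates:
    def test_weighted_mean_hand_computation(self):
        res = c14.combine_replicates([
            c14.RadiocarbonAge("a", 25000, 200),
            c14.RadiocarbonAge("b", 25500, 300),
        ])
        assert res.mean_bp == pytest.approx(25153.85, abs=0.01)
        assert res.sigma_bp == pytest.approx(166.41, abs=0.01)
        assert res.chi2_stat == pytest.approx(1.923, abs=0.001)
        assert res.passed

    def test_identical_replicates(self):
        k = 4
        res = c14.combine_replicates([c14.RadiocarbonAge(f"r{i}", 25000, 200)
                                      for i in range(k)])
        assert res.mean_bp == pytest.approx(25000)
        assert res.sigma_bp == pytest.approx(200 / math.sqrt(k))
        assert res.chi2_stat == pytest.approx(0.0)

    def test_discordant_replicates_fail(self):
        res = c14.combine_replicates([
            c14.RadiocarbonAge("a", 25000, 100),
            c14.RadiocarbonAge("b", 26000, 100),
        ])
        assert res.chi2_stat == pytest.approx(50.0)
        assert not res.passed

    def test_single_date_rejected(self):
        with pytest.raises(c14.ValidationError):
            c14.combine_replicates([c14.RadiocarbonAge("a", 25000, 100)])

    def test_combined_error_below_smallest_input(self):
        res = c14.combine_replicates([
            c14.RadiocarbonAge("a", 25000, 140),
            c14.RadiocarbonAge("b", 25100, 260),
        ])
        assert res.sigma_bp <= 140


class TestCalibrate:
    def test_identity_curve_matches_analytic_gaussian(self):
        curve = sim.synthesize_calibration_curve(4000, 6000, wiggle_amplitude=0,
                                                 err_level=1e-9)
        d = c14.calibrate(c14.RadiocarbonAge("t", 5000, 50), curve)
        analytic = np.exp(-0.5 * ((d.grid - 5000) / 50) ** 2)
        analytic /= analytic.sum()
        assert np.max(np.abs(d.prob - analytic)) < 1e-6
        (older, younger, mass) = d.hpd[0]
        assert older == 5100 and younger == 4900
        assert mass >= 0.954

    def test_out_of_range_age_rejected(self):
        curve = sim.synthesize_calibration_curve(4000, 6000)
        with pytest.raises(c14.RangeError):
            c14.calibrate(c14.RadiocarbonAge("t", 30000, 50), curve)

    def test_doubling_sigma_widens_hpd(self):
        curve = sim.synthesize_calibration_curve(3000, 8000, wiggle_amplitude=30,
                                                 wiggle_period=500, err_level=10)
        def width(sigma):
            d = c14.calibrate(c14.RadiocarbonAge("t", 5000, sigma), curve)
            return sum(older - younger for older, younger, _ in d.hpd)
        assert width(100) > width(50)


class TestHpdRanges:
    def test_two_equal_modes(self):
        grid = np.arange(0.0, 2001.0)
        p = np.exp(-0.5 * ((grid - 500) / 40) ** 2) + np.exp(-0.5 * ((grid - 1500) / 40) ** 2)
        p /= p.sum()
        d = c14.CalibratedDensity(grid=grid, prob=p)
        ranges = c14.hpd_ranges(d, 0.954)
        assert len(ranges) == 2
        for _, _, mass in ranges:
            assert mass == pytest.approx(0.477, abs=0.01)

    def test_full_mass_covers_support(self):
        grid = np.arange(0.0, 101.0)
        p = np.full_like(grid, 1 / len(grid))
        d = c14.CalibratedDensity(grid=grid, prob=p)
        ((older, younger, mass),) = c14.hpd_ranges(d, 1.0)
        assert younger <= 0 and older >= 100 and mass == pytest.approx(1.0)

    def test_requested_mass_reached(self):
        grid = np.arange(0.0, 1001.0)
        p = np.exp(-0.5 * ((grid - 500) / 60) ** 2)
        p /= p.sum()
        d = c14.CalibratedDensity(grid=grid, prob=p)
        total = sum(m for _, _, m in c14.hpd_ranges(d, 0.954))
        assert total >= 0.954

    def test_invalid_mass_rejected(self):
        grid = np.arange(0.0, 11.0)
        d = c14.CalibratedDensity(grid=grid, prob=np.full(11, 1 / 11))
        with pytest.raises(c14.ValidationError):
            c14.hpd_ranges(d, 1.5)


@pytest.fixture(scope="module")
def curve():
    return sim.synthesize_calibration_curve(20000, 40000, wiggle_amplitude=30,
                                            wiggle_period=600, err_level=15)


class TestPhaseOutlierModel:
    def _cluster_dates(self, curve, n=8, seed=7, start=31000, end=30000, sigma=120.0):
        rng = np.random.default_rng(seed)
        thetas = rng.uniform(end, start, n)
        mu, _ = curve.interp(thetas)
        return [c14.RadiocarbonAge(f"d{i}", float(rng.normal(m, sigma)), sigma)
                for i, m in enumerate(mu)]

    def test_tight_cluster_small_span_and_prior_level_o(self, curve):
        rng = np.random.default_rng(1)
        mu, _ = curve.interp(np.full(10, 30500.0))
        dates = [c14.RadiocarbonAge(f"d{i}", float(rng.normal(m, 100)), 100.0)
                 for i, m in enumerate(mu)]
        res = c14.phase_outlier_model(dates, curve, 0.05, iterations=6000,
                                      burn_in=1500, seed=2)
        assert np.median(res.span_draws) < 500
        assert np.all(res.outlier_prob < 0.2)

    def test_planted_outlier_has_maximum_o(self, curve):
        dates = self._cluster_dates(curve, n=9)
        dates.append(c14.RadiocarbonAge("out", dates[0].age_bp + 3000, 120.0))
        res = c14.phase_outlier_model(dates, curve, 0.05, iterations=6000,
                                      burn_in=1500, seed=3)
        assert int(np.argmax(res.outlier_prob)) == len(dates) - 1
        assert res.outlier_prob[-1] > 3 * np.max(res.outlier_prob[:-1])

    def test_forced_outlier_prior_one(self, curve):
        dates = self._cluster_dates(curve, n=5)
        dates.append(c14.RadiocarbonAge("forced", dates[0].age_bp, 120.0))
        priors = [0.05] * 5 + [1.0]
        res = c14.phase_outlier_model(dates, curve, priors, iterations=2000,
                                      burn_in=500, seed=4)
        assert res.outlier_prob[-1] == 1.0

    def test_boundaries_ordered_in_every_draw(self, curve):
        dates = self._cluster_dates(curve, n=6)
        res = c14.phase_outlier_model(dates, curve, 0.05, iterations=3000,
                                      burn_in=500, seed=5)
        assert np.all(res.start_draws > res.end_draws)

    def test_determinism_under_seed(self, curve):
        dates = self._cluster_dates(curve, n=5)
        a = c14.phase_outlier_model(dates, curve, 0.05, iterations=1500,
                                    burn_in=300, seed=11)
        b = c14.phase_outlier_model(dates, curve, 0.05, iterations=1500,
                                    burn_in=300, seed=11)
        np.testing.assert_array_equal(a.start_draws, b.start_draws)
        np.testing.assert_array_equal(a.outlier_prob, b.outlier_prob)

    def test_single_date_rejected(self, curve):
        with pytest.raises(c14.ValidationError):
            c14.phase_outlier_model([c14.RadiocarbonAge("a", 30000, 100)], curve)
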