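"""Turnover, isotope-dilution, clearance, SXRF and delay estimators."""

import math

import numpy as np
import pytest

import periphos as pp
from periphos.constants import AVOGADRO, PHOSPHORUS_MOLAR_MASS
from periphos.estimators import SXRF_LINEAR_RANGE
from periphos.exceptions import DegenerateDataError


class TestTurnoverTime:
    def test_one_e_folding(self):
        f = 1 - math.exp(-1)
        assert pp.turnover_time(f, 60.0) == pytest.approx(60.0, rel=1e-12)

    def test_half_depleted_in_an_hour(self):
        assert pp.turnover_time(0.5, 60.0) == pytest.approx(60.0 / math.log(2), rel=1e-12)

    def test_small_fraction_limit(self):
        # for f << 1, T ~= t / f
        assert pp.turnover_time(1e-6, 10.0) == pytest.approx(1e7, rel=1e-5)

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.1, 1.2])
    def test_rejects_out_of_range_fraction(self, f):
        with pytest.raises(ValueError):
            pp.turnover_time(f, 10.0)


class TestIsotopeDilution:
    AMBIENT = 5e-9
    VELOCITY = 1e-10  # mol l^-1 min^-1
    CONCS = (1e-9, 2e-9, 5e-9, 1e-8, 2e-8)
    TIMES = (10.0, 20.0, 40.0)

    def noiseless_series(self):
        return pp.generate_bioassay(self.AMBIENT, self.VELOCITY, self.CONCS, self.TIMES)

    def test_noiseless_recovery_is_exact(self):
        fit = pp.isotope_dilution_fit(self.noiseless_series())
        assert fit.ambient_conc == pytest.approx(self.AMBIENT, rel=1e-9)
        assert fit.uptake_velocity == pytest.approx(self.VELOCITY, rel=1e-9)

    def test_turnover_times_follow_the_dilution_line(self):
        fit = pp.isotope_dilution_fit(self.noiseless_series())
        for ca, t_hat in fit.turnover_times.items():
            assert t_hat == pytest.approx((self.AMBIENT + ca) / self.VELOCITY, rel=1e-9)

    def test_single_concentration_is_degenerate(self):
        series = pp.generate_bioassay(self.AMBIENT, self.VELOCITY, (1e-9,), self.TIMES)
        with pytest.raises(ValueError):
            pp.isotope_dilution_fit(series)

    def test_standard_errors_reported_with_enough_concentrations(self):
        fit = pp.isotope_dilution_fit(self.noiseless_series())
        assert np.isfinite(fit.ambient_se)
        assert np.isfinite(fit.velocity_se)

    def test_noisy_recovery_median_error_under_ten_percent(self):
        """5% multiplicative noise on fractions: over 100 draws the median
        relative error of both estimates stays below 10%."""
        amb_err, vel_err = [], []
        for draw in range(100):
            noise = pp.NoiseModel(kind="lognormal", sigma=0.05, seed=1000 + draw)
            series = pp.generate_bioassay(
                self.AMBIENT, self.VELOCITY, self.CONCS, self.TIMES, noise=noise
            )
            fit = pp.isotope_dilution_fit(series)
            amb_err.append(abs(fit.ambient_conc / self.AMBIENT - 1))
            vel_err.append(abs(fit.uptake_velocity / self.VELOCITY - 1))
        assert np.median(amb_err) < 0.10
        assert np.median(vel_err) < 0.10


class TestClearanceFromDepletion:
    def test_exact_exponential_recovery(self):
        params = pp.KineticParameters(clearance_cl=1.8e-13)
        rho = 2e10
        times = np.array([10.0, 30.0, 60.0, 120.0, 240.0])
        fr = pp.seawater_depletion_closed_form(params, rho, 1.0, times)
        fit = pp.clearance_from_depletion(times, fr, rho)
        assert fit.clearance_cl == pytest.approx(1.8e-13, rel=1e-9)
        assert not fit.nonmonotone_warning

    def test_detection_floor_censors_late_points(self):
        rate = 0.1
        times = np.arange(10.0, 300.0, 20.0)
        fr = np.exp(-rate * times)
        fit = pp.clearance_from_depletion(
            times, fr, 1e9, initial_conc=1e-9, detection_floor_conc=1e-15
        )
        # exp(-0.1 t) < 1e-6 beyond t ~ 138 min
        assert fit.n_used == int(np.sum(fr * 1e-9 >= 1e-15))
        assert fit.n_used < times.size
        assert fit.depletion_rate == pytest.approx(rate, rel=1e-9)

    def test_poisson_counting_noise_small_bias(self):
        """Relative bias of the fitted rate stays below 2% at 1e4 counts."""
        rate = 0.05
        times = np.arange(5.0, 65.0, 5.0)
        ests = []
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            expected = np.exp(-rate * times) * 1e4
            fr = np.clip(rng.poisson(expected) / 1e4, 1e-9, 1.0)
            fit = pp.clearance_from_depletion(times, fr, 1e9)
            ests.append(fit.depletion_rate)
        assert np.mean(ests) == pytest.approx(rate, rel=0.02)

    def test_gross_increase_raises_warning_flag(self):
        times = np.arange(5.0, 155.0, 5.0)
        fr = np.exp(-0.05 * times)
        fr[10] = min(1.0, fr[10] * 20)  # a 20x jump upward mid-series
        fit = pp.clearance_from_depletion(times, fr, 1e9)
        assert fit.nonmonotone_warning

    def test_flat_series_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pp.clearance_from_depletion(
                np.array([10.0, 20.0]), np.array([0.5, 0.5]), 1e9
            )


class TestSxrf:
    QUOTA_G = 1.93e7 * PHOSPHORUS_MOLAR_MASS / AVOGADRO  # g P per cell
    BLANK = 2e-12  # g, small against the ~1e-15 g/cell quota times 1e5 cells

    def calibration(self):
        cells = np.array([5e4, 1e5, 2e5, 4e5, 7e5])
        points = [(c, self.BLANK + c * self.QUOTA_G) for c in cells]
        return pp.SxrfCalibration.fit(points)

    def test_noiseless_calibration_recovers_quota(self):
        cal = self.calibration()
        assert cal.slope == pytest.approx(self.QUOTA_G, rel=1e-9)
        assert cal.intercept == pytest.approx(self.BLANK, rel=1e-6)
        assert cal.calibrant_atoms_per_cell() == pytest.approx(1.93e7, rel=1e-9)

    def test_quantify_exact_inside_linear_range(self):
        cal = self.calibration()
        cells = 3e5
        res = pp.sxrf_quantify(cal, self.BLANK + cells * self.QUOTA_G * 0.5, cells)
        assert res.atoms_per_cell == pytest.approx(0.5 * 1.93e7, rel=1e-9)
        assert not res.out_of_range
        assert not res.below_detection

    def test_low_cell_numbers_flagged_out_of_range(self):
        cal = self.calibration()
        res = pp.sxrf_quantify(cal, self.BLANK + 1e4 * self.QUOTA_G, 1e4)
        assert res.out_of_range

    def test_blank_level_signal_is_below_detection(self):
        cal = self.calibration()
        res = pp.sxrf_quantify(cal, self.BLANK * 0.5, 1e5)
        assert res.below_detection
        assert res.atoms_per_cell == 0.0

    def test_noisy_quantification_median_error_small(self):
        """3% signal noise: median quota error below 8% over 200 samples."""
        cal = self.calibration()
        rng = np.random.default_rng(2)
        errs = []
        for _ in range(200):
            cells = rng.uniform(*SXRF_LINEAR_RANGE)
            signal = (self.BLANK + cells * self.QUOTA_G) * rng.normal(1.0, 0.03)
            res = pp.sxrf_quantify(cal, signal, cells)
            errs.append(abs(res.atoms_per_cell / 1.93e7 - 1))
        assert np.median(errs) < 0.08


class TestGenomeEquivalents:
    def test_synechococcus_scale(self):
        # 1.93e7 P atoms against a 2.4e6 bp genome at 2 P per bp
        assert pp.genome_p_equivalents(1.93e7, 2.4e6) == pytest.approx(4.02, rel=1e-3)

    def test_p_per_bp_convention_scales_inversely(self):
        a = pp.genome_p_equivalents(1e7, 2e6, p_per_bp=2)
        b = pp.genome_p_equivalents(1e7, 2e6, p_per_bp=1)
        assert b == pytest.approx(2 * a)

    def test_rejects_nonpositive_genome(self):
        with pytest.raises(ValueError):
            pp.genome_p_equivalents(1e7, 0.0)


class TestInhibitionDelay:
    def test_exact_linear_ramp(self):
        times = np.array([1.0, 2.0, 5.0, 10.0])
        rate = 3.0
        delay = pp.estimate_inhibition_delay(times, rate * times, treated_plateau=12.0)
        assert delay == pytest.approx(4.0, rel=1e-12)

    def test_scale_equivariance(self):
        times = np.array([1.0, 2.0, 4.0])
        vals = np.array([2.0, 4.1, 7.9])
        d1 = pp.estimate_inhibition_delay(times, vals, 10.0)
        d2 = pp.estimate_inhibition_delay(times, 5 * vals, 50.0)
        assert d2 == pytest.approx(d1, rel=1e-12)

    def test_no_accumulation_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pp.estimate_inhibition_delay(np.array([1.0, 2.0]), np.array([0.0, 0.0]), 5.0)
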