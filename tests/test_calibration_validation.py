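"""Validation-statistics tests: OLS calibration diagnostics, ICH sensitivity
limits, recovery summaries, precision cells, and t/F method comparison,
checked against closed forms, brute-force oracles and published tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from synchrofluor import calibration_validation as cv
from synchrofluor import datasets
from synchrofluor.eem_core import ValidationError

BAM_LEVELS = [0.2, 0.8, 1.6, 3.2, 4.0, 6.0]


def normal_equations_oracle(x, y):
    """Independent brute-force OLS: solve X'X beta = X'y and recompute the
    textbook diagnostic formulas directly."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    a, b = beta
    n = x.size
    resid = y - X @ beta
    s_yx = math.sqrt(float(resid @ resid) / (n - 2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    s_b = s_yx / math.sqrt(sxx)
    s_a = s_yx * math.sqrt(float(np.sum(x**2)) / (n * sxx))
    return a, b, s_yx, s_a, s_b


class TestFitCalibration:
    def test_exact_line_recovers_published_coefficients(self):
        y = [18.21 + 13.65 * c for c in BAM_LEVELS]
        curve = cv.fit_calibration(BAM_LEVELS, y, analyte="BAM", wavelength=260.0)
        assert curve.a == pytest.approx(18.21, abs=1e-10)
        assert curve.b == pytest.approx(13.65, abs=1e-10)
        assert curve.r == pytest.approx(1.0, abs=1e-12)
        assert curve.s_yx == pytest.approx(0.0, abs=1e-9)

    def test_two_points_saturated_fit_warns(self):
        with pytest.warns(UserWarning, match="two-point"):
            curve = cv.fit_calibration([1.0, 2.0], [5.0, 3.0])
        assert curve.r == -1.0
        assert curve.s_yx == curve.s_a == curve.s_b == 0.0

    def test_identical_concentrations_rejected(self):
        with pytest.raises(cv.SingularDesignError):
            cv.fit_calibration([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @given(
        st.lists(
            st.floats(-50, 50).map(lambda v: round(v, 3)),
            min_size=6,
            max_size=6,
            unique=True,
        ),
        st.lists(st.floats(-100, 100), min_size=6, max_size=6),
    )
    @settings(max_examples=60, derandomize=True)
    def test_matches_normal_equations_oracle(self, x, y):
        a, b, s_yx, s_a, s_b = normal_equations_oracle(x, y)
        curve = cv.fit_calibration(x, y)
        scale = max(1.0, abs(a), abs(b), s_yx)
        assert curve.a == pytest.approx(a, rel=1e-10, abs=1e-10 * scale)
        assert curve.b == pytest.approx(b, rel=1e-10, abs=1e-10 * scale)
        assert curve.s_yx == pytest.approx(s_yx, rel=1e-10, abs=1e-10 * scale)
        assert curve.s_a == pytest.approx(s_a, rel=1e-10, abs=1e-10 * scale)
        assert curve.s_b == pytest.approx(s_b, rel=1e-10, abs=1e-10 * scale)

    def test_noiseless_simulator_fit_recovers_construction(self, models, assays, noiseless_curves):
        """Fitting a noiseless simulated series reproduces the generator's
        linear construction: intercept 0 and the unit-response slope."""
        from synchrofluor import synth_spectra as ss
        from synchrofluor.eem_core import amplitude_at

        for model in models:
            assay = assays[model.name]
            curve = noiseless_curves[model.name]
            unit = ss.unit_derivative_spectrum(model)
            slope = assay.polarity * amplitude_at(unit, assay.readout_wavelength)
            assert curve.a == pytest.approx(0.0, abs=1e-8 * abs(slope))
            assert curve.b == pytest.approx(slope, rel=1e-9)


class TestSensitivityLimits:
    @pytest.mark.parametrize(
        "s_a,b,lod_2sf", [(0.096, 13.65, 0.023), (0.464, 27.57, 0.056)]
    )
    def test_published_lod_values(self, s_a, b, lod_2sf):
        curve = cv.CalibrationCurve(
            analyte="x", wavelength=260.0, a=0.0, b=b, r=1.0,
            s_yx=0.0, s_a=s_a, s_b=0.0, n=6, range=(0.2, 6.0),
        )
        limits = cv.sensitivity_limits(curve)
        assert round(limits.lod, 3) == lod_2sf

    def test_zero_sigma_gives_zero_limits(self):
        curve = cv.CalibrationCurve(
            analyte="x", wavelength=260.0, a=0.0, b=5.0, r=1.0,
            s_yx=0.0, s_a=0.0, s_b=0.0, n=6, range=(0.2, 6.0),
        )
        limits = cv.sensitivity_limits(curve)
        assert limits.lod == limits.loq == 0.0

    def test_loq_lod_ratio_exact(self):
        curve = cv.CalibrationCurve(
            analyte="x", wavelength=260.0, a=0.0, b=7.7, r=1.0,
            s_yx=0.0, s_a=0.31, s_b=0.0, n=6, range=(0.2, 6.0),
        )
        limits = cv.sensitivity_limits(curve)
        assert limits.loq / limits.lod == pytest.approx(10.0 / 3.3, rel=1e-12)

    def test_nonpositive_slope_rejected(self):
        curve = cv.CalibrationCurve(
            analyte="x", wavelength=260.0, a=0.0, b=-2.0, r=-1.0,
            s_yx=0.0, s_a=0.1, s_b=0.0, n=6, range=(0.2, 6.0),
        )
        with pytest.raises(ValidationError):
            cv.sensitivity_limits(curve)


class TestRecoveryStats:
    def test_published_pure_form_bam_mean(self):
        recs = datasets.pure_form_recoveries("BAM")
        mean, sd, rsd, err = cv.recovery_stats(recs)
        assert round(mean, 2) == 100.15

    def test_published_pure_form_teb_sd(self):
        recs = datasets.pure_form_recoveries("TEB")
        mean, sd, rsd, err = cv.recovery_stats(recs)
        assert round(sd, 2) == 1.71

    def test_identical_records_zero_spread(self):
        mean, sd, rsd, err = cv.recovery_stats([100.0] * 5)
        assert sd == rsd == err == 0.0

    def test_record_objects_and_floats_agree(self):
        records = cv.recoveries_from_pairs([1.0, 2.0, 4.0], [1.02, 1.98, 4.04])
        as_rec = cv.recovery_stats(records)
        as_float = cv.recovery_stats([r.recovery for r in records])
        assert as_rec == as_float

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            cv.recovery_stats([100.0])


class TestMethodComparison:
    def test_identical_groups_null_statistics(self):
        mc = cv.compare_methods([99.0, 100.0, 101.0], [99.0, 100.0, 101.0])
        assert mc.t == 0.0
        assert mc.f == 1.0
        assert not mc.significant

    def test_published_pure_form_bam_t_and_f(self):
        prop = datasets.pure_form_recoveries("BAM")
        ref = datasets.PURE_FORM_REFERENCE_RECOVERIES["BAM"]
        mc = cv.compare_methods(prop, ref)
        assert round(mc.t, 2) == 0.25
        assert round(mc.f, 2) == 1.70
        assert round(mc.t_critical, 2) == 2.36
        assert round(mc.f_critical, 2) == 19.30  # printed as 19.29

    def test_published_pure_form_teb_t_and_f(self):
        prop = datasets.pure_form_recoveries("TEB")
        ref = datasets.PURE_FORM_REFERENCE_RECOVERIES["TEB"]
        mc = cv.compare_methods(prop, ref)
        assert round(mc.t, 2) == 0.66
        assert round(mc.f, 2) == 6.26
        assert not mc.significant

    def test_t_matches_scipy_pooled(self, rng):
        a = rng.normal(100, 1.5, size=6)
        b = rng.normal(100.5, 1.0, size=4)
        mc = cv.compare_methods(a, b)
        t_scipy = sps.ttest_ind(a, b, equal_var=True).statistic
        assert mc.t == pytest.approx(abs(t_scipy), rel=1e-12)
        assert mc.df_t == 8

    def test_shift_invariance(self, rng):
        a = rng.normal(100, 2, size=5)
        b = rng.normal(99, 1, size=5)
        m1 = cv.compare_methods(a, b)
        m2 = cv.compare_methods(a + 37.0, b + 37.0)
        assert m1.t == pytest.approx(m2.t, rel=1e-9)
        assert m1.f == pytest.approx(m2.f, rel=1e-9)

    def test_f_swap_invariance(self, rng):
        a = rng.normal(100, 2, size=5)
        b = rng.normal(99, 1, size=7)
        assert cv.compare_methods(a, b).f == pytest.approx(
            cv.compare_methods(b, a).f, rel=1e-12
        )
        assert cv.compare_methods(a, b).f >= 1.0

    def test_both_groups_constant_reports_f_one(self):
        mc = cv.compare_methods([5.0, 5.0, 5.0], [7.0, 7.0])
        assert mc.f == 1.0

    def test_undersized_group_rejected(self):
        with pytest.raises(ValidationError):
            cv.student_t([100.0], [99.0, 100.0])


class TestPrecisionStudy:
    def test_equal_replicates_zero_spread(self):
        cells = cv.precision_study({("d1", 1.0): [100.0, 100.0, 100.0]})
        (cell,) = cells
        assert cell.sd == cell.rsd == cell.error == 0.0
        assert cell.mode == "intra-day"

    def test_error_is_rsd_over_sqrt_n(self):
        """%error = %RSD / sqrt(n): with %RSD 1.70 at n = 6 this gives 0.69."""
        rng = np.random.default_rng(7)
        base = 100 + 1.7 * rng.standard_normal(6)
        # scale the set so its %RSD is exactly 1.70
        mean, sd, rsd, _ = cv.recovery_stats(base)
        scaled = mean + (base - mean) * (1.70 / rsd)
        cells = cv.precision_study({("d1", 2.0): scaled})
        assert round(cells[0].rsd, 2) == 1.70
        assert round(cells[0].error, 2) == 0.69

    def test_cells_match_loop_oracle(self, rng):
        sets = {
            (day, conc): rng.normal(100, 1.2, size=3)
            for day in ("d1", "d2")
            for conc in (0.4, 3.2, 6.0)
        }
        cells = cv.precision_study(sets)
        intra = {(c.day, c.concentration): c for c in cells if c.mode == "intra-day"}
        assert set(intra) == set(sets)
        for key, vals in sets.items():
            cell = intra[key]
            assert cell.mean_recovery == pytest.approx(np.mean(vals), rel=1e-12)
            assert cell.sd == pytest.approx(np.std(vals, ddof=1), rel=1e-12)
            assert cell.rsd == pytest.approx(100 * cell.sd / cell.mean_recovery, rel=1e-12)
            assert cell.error == pytest.approx(cell.rsd / math.sqrt(3), rel=1e-12)
        inter = [c for c in cells if c.mode == "inter-day"]
        assert {c.concentration for c in inter} == {0.4, 3.2, 6.0}
        for cell in inter:
            pooled = np.concatenate(
                [sets[(d, cell.concentration)] for d in ("d1", "d2")]
            )
            assert cell.mean_recovery == pytest.approx(np.mean(pooled), rel=1e-12)
            assert cell.n == 6

    def test_singleton_cell_rejected(self):
        with pytest.raises(ValidationError):
            cv.precision_study({("d1", 1.0): [100.0]})


class TestSlopeRecoveryMonteCarlo:
    def test_noisy_slope_estimate_is_unbiased(self, models, assays):
        """With default noise, the OLS slope over 200 seeded calibration sets
        is unbiased within two Monte-Carlo standard errors."""
        from synchrofluor import quantitation as qt
        from synchrofluor import synth_spectra as ss
        from synchrofluor.eem_core import amplitude_at

        bam, _ = models
        assay = assays["BAM"]
        noise = ss.default_noise_model(models)
        unit = ss.unit_derivative_spectrum(bam)
        true_b = assay.polarity * amplitude_at(unit, assay.readout_wavelength)
        slopes = []
        for rep in range(200):
            samples = ss.generate_calibration_set(bam, noise=noise, seed=20_000 + rep)
            amps = [qt.measure(s.eem, assay) for s in samples]
            concs = [s.concentrations["BAM"] for s in samples]
            slopes.append(cv.fit_calibration(concs, amps).b)
        slopes = np.asarray(slopes)
        mc_se = slopes.std(ddof=1) / math.sqrt(slopes.size)
        assert abs(slopes.mean() - true_b) < 2.0 * mc_se
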