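"""Curve fitting and half-value extraction: fit recovery, HVL/HVD solvers,
attenuation coefficients, and the kV-trend and cross-material fits."""

import numpy as np
import pytest

from radqc import attenuation as att
from radqc import beam_sim as bs


def make_series(thicknesses, kerma, **kw):
    return att.TransmissionSeries(
        tube_voltage=kw.pop("kv", 80.0),
        thicknesses_cm=np.asarray(thicknesses, float),
        kerma_rates=np.asarray(kerma, float),
        **kw,
    )


T_GRID = np.arange(0.0, 5.01, 0.5)


class TestSeriesValidation:
    def test_requires_zero_and_five_thicknesses(self):
        with pytest.raises(ValueError):
            make_series([0.5, 1.0, 1.5, 2.0, 2.5], np.ones((5, 3)))
        with pytest.raises(ValueError):
            make_series([0.0, 0.5, 1.0, 1.5], np.ones((4, 3)))

    def test_positive_kerma_required(self):
        k = np.ones((11, 3))
        k[3, 1] = -1.0
        with pytest.raises(ValueError):
            make_series(T_GRID, k)

    def test_nonmonotone_mean_warns_not_errors(self):
        k = np.exp(-0.3 * T_GRID)[:, None] * np.ones((1, 3))
        k[5] *= 1.5  # bump one mean upward
        with pytest.warns(UserWarning):
            make_series(T_GRID, k)


class TestAverageRepeats:
    @pytest.mark.parametrize("repeats,expected", [((10, 10, 10), 10.0), ((9, 10, 11), 10.0)])
    def test_arithmetic_mean(self, repeats, expected):
        k = np.tile(np.array(repeats, float), (11, 1)) * np.exp(-0.3 * T_GRID)[:, None]
        s = make_series(T_GRID, k)
        _, means = att.average_repeats(s)
        assert means[0] == pytest.approx(expected * 1.0)

    def test_noiseless_simulation_means_equal_model(self, noiseless_experiment, default_spectra):
        s = noiseless_experiment.series[0]
        _, means = att.average_repeats(s)
        model = default_spectra[s.tube_voltage]
        expected = 30.0 * np.array(
            [bs.spectrum_transmission(model, t) for t in s.thicknesses_cm]
        )
        assert np.allclose(means, expected, rtol=1e-12)


class TestDoubleExponentialFit:
    def test_nests_single_exponential(self):
        y = 100.0 * np.exp(-0.3466 * T_GRID)
        fit = att.fit_double_exponential(T_GRID, y)
        assert fit.rmse < 1e-6
        assert fit.zero_value == pytest.approx(100.0, abs=1e-4)
        assert fit.converged

    def test_constant_curve_degenerates_to_zero_rates(self):
        fit = att.fit_double_exponential(T_GRID, np.full_like(T_GRID, 100.0))
        assert fit(3.0) == pytest.approx(100.0, rel=1e-6)
        with pytest.raises(att.NonAttenuatingFitError):
            att.solve_hvl(fit)

    def test_recovers_two_term_parameters(self):
        a = (60.0, 40.0)
        m = (0.5, 0.2)
        y = a[0] * np.exp(-m[0] * T_GRID) + a[1] * np.exp(-m[1] * T_GRID)
        fit = att.fit_double_exponential(T_GRID, y)
        assert fit.a1 == pytest.approx(a[0], rel=1e-3)
        assert fit.m1 == pytest.approx(m[0], rel=1e-3)
        assert fit.a2 == pytest.approx(a[1], rel=1e-3)
        assert fit.m2 == pytest.approx(m[1], rel=1e-3)

    def test_canonical_ordering(self):
        fit = att.DoubleExpFit(a1=1.0, m1=0.1, a2=2.0, m2=0.9, rmse=0.0, converged=True)
        assert fit.m1 >= fit.m2
        assert (fit.a1, fit.m1) == (2.0, 0.9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            att.fit_double_exponential(np.array([0.0, 1.0, 2.0]), np.array([3.0, 2.0, 1.0]))


class TestSolveHvl:
    def test_single_term_ln2_over_m(self):
        fit = att.DoubleExpFit(a1=100.0, m1=0.3466, a2=0.0, m2=0.0, rmse=0.0, converged=True)
        assert att.solve_hvl(fit) == pytest.approx(10 * np.log(2) / 0.3466, abs=1e-3)

    def test_against_independent_grid_bisection_oracle(self):
        # equal-amplitude mixture, rates per mm; solve on a mm axis directly
        fit = att.DoubleExpFit(a1=0.5, m1=0.05, a2=0.5, m2=0.02, rmse=0.0, converged=True)

        def curve(t):
            return 0.5 * np.exp(-0.05 * t) + 0.5 * np.exp(-0.02 * t)

        lo, hi = 0.0, 100.0
        for _ in range(200):  # plain interval-halving oracle
            mid = 0.5 * (lo + hi)
            if curve(mid) > 0.5:
                lo = mid
            else:
                hi = mid
        oracle = 0.5 * (lo + hi)
        assert att.solve_hvl(fit, unit_scale=1.0) == pytest.approx(oracle, abs=1e-8)

    def test_root_residual_defining_property(self):
        fit = att.DoubleExpFit(a1=70.0, m1=0.6, a2=30.0, m2=0.15, rmse=0.0, converged=True)
        hvl_cm = att.solve_hvl(fit) / 10.0
        assert fit(hvl_cm) == pytest.approx(0.5 * fit.zero_value, rel=1e-9)

    def test_measured_reference_alternative(self):
        fit = att.DoubleExpFit(a1=50.0, m1=0.5, a2=50.0, m2=0.2, rmse=0.0, converged=True)
        default = att.solve_hvl(fit)
        measured = att.solve_hvl(fit, reference_value=90.0)
        # a lower reference level halves at a deeper thickness
        assert measured > default


class TestMuAndHvd:
    @pytest.mark.parametrize(
        "hvl,expected",
        [(20.1, 0.0345), (6.2, 0.112), (np.log(2), 1.0)],
    )
    def test_mu_from_hvl(self, hvl, expected):
        assert float(f"{att.compute_mu(hvl):.3g}") == pytest.approx(expected)

    def test_mu_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            att.compute_mu(0.0)

    def test_mu_antitone_in_hvl(self):
        hvls = np.linspace(5.0, 30.0, 20)
        mus = [att.compute_mu(h) for h in hvls]
        assert np.all(np.diff(mus) < 0)

    @pytest.mark.parametrize(
        "hvl_mm,expected", [(20.1, 2.37), (27.0, 3.19)]
    )
    def test_hvd_from_hvl_reference_values(self, hvl_mm, expected):
        hvd = att.hvd_from_hvl(hvl_mm, 0.590, 0.5)
        assert float(f"{hvd:.3g}") == pytest.approx(expected)

    def test_hvd_unit_case(self):
        # HVL of exactly one article thickness -> HVD is one article's areal density
        assert att.hvd_from_hvl(5.0, 0.614, 0.5) == pytest.approx(0.614)

    def test_hvd_dual_path_agreement(self, noiseless_experiment):
        """Refit on the areal-density axis agrees with nominal scaling."""
        for s in noiseless_experiment.series[::3]:
            t, means = att.average_repeats(s)
            fit = att.fit_double_exponential(t, means)
            via_scaling = att.hvd_from_hvl(
                att.solve_hvl(fit), s.areal_density_per_article, s.article_thickness_cm
            )
            via_refit = att.compute_hvd(s)
            assert via_refit == pytest.approx(via_scaling, rel=1e-6)

    def test_hvd_requires_areal_density(self):
        y = 100.0 * np.exp(-0.3 * T_GRID)
        s = make_series(T_GRID, y[:, None])
        with pytest.raises(ValueError):
            att.compute_hvd(s)


class TestTrendFits:
    def test_quadratic_exact_interpolation(self):
        kv = np.array([50.0, 60, 70, 80, 90, 100, 110, 120])
        y = 1e-4 * kv**2 - 0.01 * kv + 3.0
        t = att.fit_quadratic_trend(kv, y)
        assert (t.a, t.b, t.c) == pytest.approx((1e-4, -0.01, 3.0), abs=1e-9)

    def test_quadratic_constant_data(self):
        t = att.fit_quadratic_trend([50.0, 80.0, 120.0], [2.0, 2.0, 2.0])
        assert (t.a, t.b, t.c) == pytest.approx((0.0, 0.0, 2.0), abs=1e-12)

    def test_quadratic_order_invariance(self):
        kv = np.array([50.0, 70, 90, 110])
        y = np.array([2.0, 2.2, 2.5, 2.6])
        t1 = att.fit_quadratic_trend(kv, y)
        t2 = att.fit_quadratic_trend(kv[::-1], y[::-1])
        assert (t1.a, t1.b, t1.c) == pytest.approx((t2.a, t2.b, t2.c), rel=1e-12)

    def test_quadratic_needs_three_abscissae(self):
        with pytest.raises(ValueError):
            att.fit_quadratic_trend([50.0, 50.0, 60.0], [1.0, 1.0, 2.0])

    def test_line_exact_on_perfect_line(self):
        x = np.array([2.0, 3.0, 5.0, 6.0])
        fit = att.fit_cross_material_line(np.column_stack([x, 2 * x + 15]))
        assert (fit.slope, fit.intercept) == pytest.approx((2.0, 15.0), abs=1e-12)

    def test_line_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(2, 7, 12)
        y = 1.9 * x + 15 + rng.normal(0, 0.3, 12)
        fit = att.fit_cross_material_line(np.column_stack([x, y]))
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert fit.slope == pytest.approx(sxy / sxx, rel=1e-12)
        assert fit.intercept == pytest.approx(y.mean() - sxy / sxx * x.mean(), rel=1e-12)

    def test_line_degenerate_abscissae(self):
        with pytest.raises(ValueError):
            att.fit_cross_material_line([(3.0, 20.0), (3.0, 21.0)])


class TestBeamQualityTable:
    def test_round_trip_recovers_ground_truth(self, noiseless_experiment):
        records = att.build_beam_quality_table(noiseless_experiment.series)
        for r in records:
            truth = noiseless_experiment.ground_truth_hvl_mm[r.tube_voltage]
            assert abs(r.hvl_specimen_mm - truth) / truth < 1e-3

    def test_record_invariant_mu_hvl(self, noiseless_experiment):
        for r in att.build_beam_quality_table(noiseless_experiment.series[:3]):
            assert r.mu_specimen_per_mm * r.hvl_specimen_mm == pytest.approx(np.log(2))
            assert r.mu_al_per_mm * r.hvl_al_mm == pytest.approx(np.log(2))

    def test_duplicate_kv_rejected(self, noiseless_experiment):
        s = noiseless_experiment.series[0]
        with pytest.raises(ValueError):
            att.build_beam_quality_table([s, s])

    def test_empty_input(self):
        assert att.build_beam_quality_table([]) == []
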