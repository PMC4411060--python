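"""DPPH assay mathematics and bioconversion kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxyfun import reference_data
from oxyfun.assaykit import (AntioxidantResult, DoseResponse, KineticTrace,
                             TimeCourse, antioxidant_summary,
                             antiradical_efficiency, dose_response_from_traces,
                             fit_ec50, formation_rate, load_dose_response,
                             load_timecourse, load_traces, percent_dpph_reduced,
                             tec50, yield_and_distribution)
from oxyfun.errors import PlateauError, RangeError


def trace(times, absorbance, ratio=0.3, **kw):
    return KineticTrace(times=np.asarray(times, float),
                        absorbance_515=np.asarray(absorbance, float),
                        antioxidant_ratio=ratio, **kw)


class TestPercentReduced:
    @pytest.mark.parametrize("a30,expected", [(0.6, 50.0), (1.2, 0.0), (0.0, 100.0)])
    def test_formula(self, a30, expected):
        tr = trace([0, 15, 30], [1.2, (1.2 + a30) / 2, a30])
        assert percent_dpph_reduced(tr, 30.0) == pytest.approx(expected)

    def test_interpolates_between_samples(self):
        tr = trace([0, 20, 40], [1.0, 0.6, 0.2])
        assert percent_dpph_reduced(tr, 30.0) == pytest.approx(60.0)

    def test_t_end_outside_range(self):
        tr = trace([5, 15, 30], [1.0, 0.8, 0.6])
        with pytest.raises(RangeError):
            percent_dpph_reduced(tr, 2.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_invariant_to_joint_rescaling(self, scale):
        """Rescaling absorbance and extinction together cancels in the ratio."""
        a = [1.2, 0.9, 0.5]
        t1 = trace([0, 15, 30], a, extinction_515=12.0)
        t2 = trace([0, 15, 30], [x * scale for x in a], extinction_515=12.0 * scale)
        assert percent_dpph_reduced(t1, 30) == pytest.approx(percent_dpph_reduced(t2, 30))

    def test_monotone_decreasing_in_final_absorbance(self):
        reds = [percent_dpph_reduced(trace([0, 30], [1.2, a]), 30)
                for a in (0.2, 0.5, 0.9)]
        assert reds == sorted(reds, reverse=True)


class TestFitEC50:
    def test_noiseless_hill_data_recovered_exactly(self):
        r = np.array([0.05, 0.1, 0.2, 0.3, 0.5, 0.8])
        y = 100.0 * r / (0.30 + r)
        fit = fit_ec50(DoseResponse(ratios=r, percent_reduced=y))
        assert fit.ec50 == pytest.approx(0.300, abs=1e-6)
        assert fit.model == "hill"

    def test_stoichiometric_titration_recovered(self):
        """Generator truth EC50 = 0.5/sigma for the clipped-linear response."""
        from oxyfun.synthgen import TraceSpec, simulate_dpph
        traces, truth = simulate_dpph(TraceSpec(stoichiometric_factor=2.0,
                                                noise_sd=0.01, seed=7))
        fit = fit_ec50(dose_response_from_traces(traces))
        assert fit.ec50 == pytest.approx(truth["ec50_true"], rel=0.10)

    def test_low_responses_flagged_not_silent(self):
        r = np.array([0.01, 0.02, 0.04, 0.08])
        y = np.array([2.0, 4.0, 8.0, 15.0])
        with pytest.warns(UserWarning, match="extrapolation"):
            fit = fit_ec50(DoseResponse(ratios=r, percent_reduced=y))
        assert fit.extrapolated

    def test_needs_four_distinct_ratios(self):
        with pytest.raises(ValueError):
            fit_ec50(DoseResponse(ratios=np.array([0.1, 0.2, 0.3]),
                                  percent_reduced=np.array([20, 40, 60.0])))

    def test_negative_noise_clipped_but_raw_kept(self):
        dr = DoseResponse(ratios=np.array([0.1, 0.2, 0.4, 0.8]),
                          percent_reduced=np.array([-2.0, 30.0, 60.0, 95.0]))
        assert dr.percent_reduced[0] == 0.0
        assert dr.raw_percent[0] == -2.0


class TestTec50:
    def test_flat_trace_returns_first_timepoint(self):
        tr = trace([0, 5, 10, 15], [0.8, 0.8, 0.8, 0.8])
        assert tec50(tr) == 0.0

    def test_analytic_exponential_crossing_time(self):
        """A(t) = Af + (A0-Af) exp(-t/tau) with tol 1% crosses at tau*ln(100)."""
        tau = 4.0
        t = np.arange(0.0, 40.5, 0.5)
        a = 0.3 + 0.9 * np.exp(-t / tau)
        got = tec50(trace(t, a), plateau_tol=0.01)
        assert abs(got - tau * np.log(100.0)) <= 0.5 + 1e-9  # one sampling interval

    def test_monotone_increasing_trace_raises(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(PlateauError):
            tec50(trace(t, 0.1 + 0.05 * t))

    def test_linear_decay_without_plateau_raises(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(PlateauError):
            tec50(trace(t, 1.0 - 0.05 * t))


class TestAntiradicalEfficiency:
    @pytest.mark.parametrize("ec50,t50,expected,digits", [
        (1.00, 25.3, 0.040, 3),   # weakest phenol in the published table
        (1.0, 1.0, 1.0, 6),
    ])
    def test_formula_and_rounding(self, ec50, t50, expected, digits):
        assert round(antiradical_efficiency(ec50, t50), digits) == pytest.approx(expected)

    def test_hydroxytyrosol_within_printed_sd(self):
        ae = antiradical_efficiency(0.21, 18.0)
        assert ae == pytest.approx(0.2646, abs=1e-4)
        assert abs(ae - 0.27) <= 0.01   # printed value and SD

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            antiradical_efficiency(0.0, 10.0)
        with pytest.raises(ValueError):
            antiradical_efficiency(1.0, -5.0)

    def test_result_invariant_enforced(self):
        with pytest.raises(ValueError):
            AntioxidantResult(ec50=1.0, tec50=2.0, ae=1.0)

    def test_summary_reports_both_conventions(self):
        results = [AntioxidantResult(ec50=e, tec50=t, ae=1.0 / (e * t))
                   for e, t in [(0.35, 20.0), (0.45, 18.0)]]
        out = antioxidant_summary(results)
        assert out["ae_per_replicate_mean"] == pytest.approx(
            (1 / (0.35 * 20) + 1 / (0.45 * 18)) / 2)
        assert out["ae_of_means"] == pytest.approx(1 / (0.40 * 19.0))


class TestFormationRate:
    def test_exact_on_noiseless_line(self):
        t = np.arange(0.0, 130.0, 10.0)
        tc = TimeCourse(times=t, concentrations={"p": 1.79 * t}, substrate_initial=2000.0)
        fit = formation_rate(tc, "p")
        assert fit.rate == pytest.approx(1.79, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_window_auto_truncates_at_linear_boundary(self):
        from oxyfun.synthgen import simulate_timecourse
        tc = simulate_timecourse({"p": 1.0}, linear_until=120.0, noise_sd=0.0)
        fit = formation_rate(tc, "p")
        assert abs(fit.window_end - 120.0) <= 10.0   # one sample interval
        assert fit.rate == pytest.approx(1.0, abs=1e-9)

    def test_two_point_series_flagged(self):
        tc = TimeCourse(times=np.array([0.0, 10.0]),
                        concentrations={"p": np.array([0.0, 5.0])},
                        substrate_initial=100.0)
        fit = formation_rate(tc, "p")
        assert fit.rate == pytest.approx(0.5)
        assert any("two-point" in f for f in fit.flags)

    def test_negative_slope_warns(self):
        t = np.arange(0.0, 60.0, 10.0)
        tc = TimeCourse(times=t, concentrations={"p": 50.0 - 0.5 * t},
                        substrate_initial=100.0)
        with pytest.warns(UserWarning, match="negative"):
            fit = formation_rate(tc, "p", window=60.0)
        assert "negative formation rate beyond noise" in fit.flags


class TestYieldAndDistribution:
    def test_single_product_reproduces_published_phthalan_yield(self):
        t = np.arange(0.0, 130.0, 10.0)
        tc = TimeCourse(times=t, concentrations={"DHiBF": 1.79 * t},
                        substrate_initial=2000.0)
        y, dist = yield_and_distribution(tc, 120.0)
        assert y == pytest.approx(10.74, abs=1e-9)
        assert abs(y - 10.8) <= 0.2          # printed value and SD
        assert dist == {"DHiBF": pytest.approx(100.0)}

    def test_three_products_reproduce_published_total_yield(self):
        t = np.arange(0.0, 130.0, 10.0)
        tc = TimeCourse(times=t,
                        concentrations={k: v * t for k, v in
                                        reference_data.PHENOXYETHANOL_RATES.items()},
                        substrate_initial=2000.0)
        y, dist = yield_and_distribution(tc, 120.0)
        assert y == pytest.approx(15.3, abs=1e-9)
        assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 5.0), min_size=1, max_size=5),
           st.floats(10.0, 120.0))
    def test_distribution_always_sums_to_100(self, rates, at):
        t = np.arange(0.0, 130.0, 10.0)
        tc = TimeCourse(times=t,
                        concentrations={f"p{i}": r * t for i, r in enumerate(rates)},
                        substrate_initial=5000.0)
        _, dist = yield_and_distribution(tc, at)
        assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_product_raises(self):
        tc = TimeCourse(times=np.array([0.0, 10.0]),
                        concentrations={"p": np.zeros(2)}, substrate_initial=100.0)
        with pytest.raises(ZeroDivisionError):
            yield_and_distribution(tc, 5.0)


class TestCSVInterchange:
    def test_traces_round_trip(self, tmp_path):
        from oxyfun.synthgen import TraceSpec, simulate_dpph, write_traces_csv
        traces, _ = simulate_dpph(TraceSpec(seed=3, doses=(0.1, 0.3)))
        path = tmp_path / "traces.csv"
        write_traces_csv(traces, path, header_meta={"seed": 3})
        back = load_traces(path)
        assert len(back) == 2
        orig = {t.antioxidant_ratio: t for t in traces}
        for t in back:
            np.testing.assert_allclose(t.absorbance_515,
                                       orig[t.antioxidant_ratio].absorbance_515,
                                       atol=1e-6)

    def test_timecourse_round_trip_and_area_conversion(self, tmp_path):
        from oxyfun.synthgen import simulate_timecourse, write_timecourse_csv
        tc = simulate_timecourse({"a": 1.0, "b": 0.5}, noise_sd=0.0)
        path = tmp_path / "tc.csv"
        write_timecourse_csv(tc, path)
        back = load_timecourse(path, substrate_initial=2000.0)
        np.testing.assert_allclose(back.concentrations["a"], tc.concentrations["a"],
                                   atol=1e-6)
        # peak-area variant with surrogate extinction coefficients
        area_csv = tmp_path / "area.csv"
        area_csv.write_text("time_min,product,area\n0,x,0\n10,x,24\n20,x,48\n")
        tc2 = load_timecourse(area_csv, substrate_initial=100.0,
                              surrogate_extinction={"x": 12.0}, area_scale=1.0)
        np.testing.assert_allclose(tc2.concentrations["x"], [0.0, 2.0, 4.0])

    def test_dose_response_csv(self, tmp_path):
        path = tmp_path / "dr.csv"
        path.write_text("ratio,percent_reduced,replicate\n0.1,20,0\n0.2,40,0\n"
                        "0.4,75,0\n0.8,98,0\n")
        dr = load_dose_response(path)
        fit = fit_ec50(dr)
        assert 0.2 < fit.ec50 < 0.35
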