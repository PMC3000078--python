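"""DLS aggregation: growth fits, Arrhenius law, denaturation comparison."""

import math

import numpy as np
import pytest

from calorikin import (
    ProbeTrace,
    compare_with_denaturation,
    fit_aggregation_arrhenius,
    fit_growth,
    half_life,
    scan_growth_overlay,
)
from calorikin.aggregation import AggregationFit
from calorikin.synth import GeneratorConfig, make_dls_set

LN2 = math.log(2.0)


@pytest.fixture(scope="module")
def clean_dls():
    return make_dls_set(GeneratorConfig(), seed=3, noise=0.0)


@pytest.fixture(scope="module")
def noisy_dls():
    return make_dls_set(GeneratorConfig(), seed=3, noise=0.03)


class TestFitGrowth:
    def test_noiseless_self_fit(self, clean_dls):
        for trace, truth in zip(clean_dls["temperature_series"],
                                clean_dls["truth"]["temperature_series"]):
            fit = fit_growth(trace)
            assert fit.growing
            assert fit.t_2R == pytest.approx(truth["t_2R"], rel=1e-8)
            assert fit.t_0 == pytest.approx(truth["t_0"], abs=1e-6)
            assert fit.R_h0 == pytest.approx(truth["R_h0"], rel=1e-8)

    def test_three_percent_noise_recovery(self, noisy_dls):
        # doubling time at 44 degC recovered within the reproducibility
        # half-width of repeated runs
        for trace, truth in zip(noisy_dls["concentration_series"],
                                noisy_dls["truth"]["concentration_series"]):
            fit = fit_growth(trace)
            assert fit.t_2R == pytest.approx(truth["t_2R"], abs=0.4)

    def test_time_shift_moves_only_the_lag(self, clean_dls):
        trace = clean_dls["temperature_series"][2]
        shifted = ProbeTrace(trace.abscissa + 5.0, trace.ordinate,
                             hold_temperature=trace.hold_temperature)
        a = fit_growth(trace)
        b = fit_growth(shifted)
        assert b.t_0 == pytest.approx(a.t_0 + 5.0, abs=1e-6)
        assert b.t_2R == pytest.approx(a.t_2R, rel=1e-8)
        assert b.R_h0 == pytest.approx(a.R_h0, rel=1e-8)

    def test_non_growing_trace_flagged(self):
        t = np.linspace(0, 20, 30)
        trace = ProbeTrace(t, np.full(30, 20.0), hold_temperature=317.15)
        fit = fit_growth(trace)
        assert not fit.growing


class TestAggregationArrhenius:
    def test_noiseless_recovery_of_growth_law(self, clean_dls):
        fits = [fit_growth(tr) for tr in clean_dls["temperature_series"]]
        arr = fit_aggregation_arrhenius(fits)
        law = clean_dls["truth"]["arrhenius"]
        assert arr.E_a == pytest.approx(law.E_a, rel=1e-6)
        assert arr.T_star == pytest.approx(law.T_star, rel=1e-6)

    def test_doubling_time_at_T_star_is_ln2(self, clean_dls):
        fits = [fit_growth(tr) for tr in clean_dls["temperature_series"]]
        arr = fit_aggregation_arrhenius(fits)
        t2R_at_Tstar = LN2 / arr.kinetics.rate(arr.T_star)
        assert t2R_at_Tstar == pytest.approx(LN2)

    def test_consistent_extra_point_changes_nothing(self, clean_dls):
        fits = [fit_growth(tr) for tr in clean_dls["temperature_series"]]
        arr = fit_aggregation_arrhenius(fits)
        law = clean_dls["truth"]["arrhenius"]
        T_new = 315.15
        extra = AggregationFit(3.0, 20.0, LN2 / law.rate(T_new), T_new, 0.1)
        arr2 = fit_aggregation_arrhenius(fits + [extra])
        assert arr2.E_a == pytest.approx(arr.E_a, rel=1e-6)
        assert arr2.T_star == pytest.approx(arr.T_star, rel=1e-6)

    def test_too_few_temperatures_rejected(self, clean_dls):
        fits = [fit_growth(tr) for tr in clean_dls["temperature_series"][:2]]
        with pytest.raises(ValueError):
            fit_aggregation_arrhenius(fits)

    def test_concentration_independence(self, noisy_dls):
        # traces differing only in lag return the same doubling time
        t2Rs = [fit_growth(tr).t_2R for tr in noisy_dls["concentration_series"]]
        assert max(t2Rs) - min(t2Rs) < 0.8  # within +/- the 0.4 CI half-width


class TestCompareWithDenaturation:
    def test_rate_limiting_transition_identified(self, clean_dls, s1_model):
        fits = [fit_growth(tr) for tr in clean_dls["temperature_series"]]
        arr = fit_aggregation_arrhenius(fits)
        table = compare_with_denaturation(arr, s1_model)
        mean_dev = table.groupby("transition")["relative_deviation"].mean()
        assert mean_dev.idxmin() == "domain 2 stage 1"
        # the stage-1 half-life at 44 degC lies within the printed t_2R band
        d2s1 = s1_model.domains[1].stage1
        t05 = half_life(d2s1, 317.15)
        row = table[(np.isclose(table.temperature_K, 318.15))
                    & (table.transition == "domain 2 stage 1")]
        assert not row.empty
        assert t05 == pytest.approx(4.7, abs=0.1)

    def test_wrong_domain_deviates_much_more(self, clean_dls, s1_model):
        fits = [fit_growth(tr) for tr in clean_dls["temperature_series"]]
        arr = fit_aggregation_arrhenius(fits)
        table = compare_with_denaturation(arr, s1_model)
        mean_dev = table.groupby("transition")["relative_deviation"].mean()
        assert mean_dev["domain 1"] > 3.0 * mean_dev["domain 2 stage 1"]

    def test_identical_laws_have_zero_deviation(self, s1_model):
        d2s1 = s1_model.domains[1].stage1
        temps = [314.15, 316.15, 318.15, 320.15]
        fits = [AggregationFit(3.0, 20.0, LN2 / d2s1.rate(T), T, 0.1) for T in temps]
        arr = fit_aggregation_arrhenius(fits)
        table = compare_with_denaturation(arr, s1_model)
        sub = table[table.transition == "domain 2 stage 1"]
        assert np.max(sub.relative_deviation) < 1e-6


class TestScanOverlay:
    def test_built_in_nucleation_delay_recovered(self, clean_dls, s1_model):
        report = scan_growth_overlay(clean_dls["scan_trace"], s1_model, 1.0)
        assert report["delays_K"]["transition 2"] == pytest.approx(3.0, abs=0.2)

    def test_zero_delay_when_onset_coincides(self, clean_dls, s1_model):
        # shift the trace so its onset sits exactly on the midpoint
        trace = clean_dls["scan_trace"]
        delay = scan_growth_overlay(trace, s1_model, 1.0)["delays_K"]["transition 2"]
        shifted = ProbeTrace(trace.abscissa - delay, trace.ordinate)
        report = scan_growth_overlay(shifted, s1_model, 1.0)
        assert report["delays_K"]["transition 2"] == pytest.approx(0.0, abs=0.1)

    def test_conversion_curves_non_decreasing(self, clean_dls, s1_model):
        report = scan_growth_overlay(clean_dls["scan_trace"], s1_model, 1.0)
        for conv in report["conversions"].values():
            assert np.all(np.diff(conv) >= -1e-9)
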