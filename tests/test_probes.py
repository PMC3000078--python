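"""Fluorescence parameter A, phase plots, inactivation kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calorikin import (
    FluorescenceScan,
    ProbeTrace,
    arrhenius_rate,
    compute_parameter_a,
    fit_inactivation,
    overlay_with_dsc,
    parametric_plot,
)
from calorikin.curves import CurveValidationError
from calorikin.probes import InactivationSeries
from calorikin.synth import GeneratorConfig, make_probe_set


@pytest.fixture(scope="module")
def probe_set():
    return make_probe_set(GeneratorConfig(), seed=5)


@pytest.fixture(scope="module")
def fluor_scan(probe_set):
    return FluorescenceScan.from_trace(probe_set["fluorescence"])


class TestParameterA:
    def test_plateaus_attained_exactly(self, probe_set, fluor_scan):
        A, A_norm = compute_parameter_a(fluor_scan)
        lo, _, hi = probe_set["truth"]["A_levels"]
        assert A.min() == pytest.approx(lo, rel=1e-9)
        assert A.max() == pytest.approx(hi, rel=1e-9)
        assert A_norm.min() == 0.0 and A_norm.max() == 1.0

    def test_flat_channels_rejected(self):
        T = np.linspace(290, 350, 30)
        I = np.linspace(100, 60, 30)
        with pytest.raises(CurveValidationError):
            compute_parameter_a(FluorescenceScan(T, I, I))

    @given(gain=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_gain_invariance(self, gain):
        scan = FluorescenceScan.from_trace(
            make_probe_set(GeneratorConfig(), seed=5)["fluorescence"])
        _, base = compute_parameter_a(scan)
        scaled = FluorescenceScan(scan.temperature, gain * scan.I320, gain * scan.I365)
        _, again = compute_parameter_a(scaled)
        np.testing.assert_allclose(again, base, atol=1e-9)


class TestParametricPlot:
    def test_three_state_trace_has_flanking_origin_segments(self, fluor_scan):
        segments = parametric_plot(fluor_scan)
        assert segments[0].through_origin
        assert segments[-1].through_origin
        transitions = [s for s in segments if not s.through_origin]
        assert len(transitions) >= 1
        lo = min(s.temperature_range[0] for s in transitions)
        hi = max(s.temperature_range[1] for s in transitions)
        # transition region of the reference model (both stages), +/- ~1 K
        assert 312.0 < lo < 319.0
        assert 323.0 < hi < 330.0

    def test_pure_quenching_single_origin_segment(self):
        T = np.linspace(290, 350, 40)
        I365 = np.linspace(100, 55, 40)
        I320 = 1.1 * I365
        segments = parametric_plot(FluorescenceScan(T, I320, I365))
        assert len(segments) == 1
        assert segments[0].through_origin

    def test_adjacent_transitions_split_at_derivative_valley(self):
        # two sequential sigmoid steps of A (no plateau between), like
        # two denaturation stages following each other
        T = np.linspace(290.0, 350.0, 121)
        step1 = 1.0 / (1.0 + np.exp(-(T - 319.0) / 0.8))
        step2 = 1.0 / (1.0 + np.exp(-(T - 325.0) / 0.8))
        A = 1.06 + 0.13 * step1 + 0.13 * step2
        quench = 1.0 - 0.5 * (T - T[0]) / (T[-1] - T[0])
        I365 = 100.0 * quench
        segments = parametric_plot(FluorescenceScan(T, A * I365, I365))
        transitions = [s for s in segments if not s.through_origin]
        assert len(transitions) == 2
        assert transitions[0].temperature_range[0] == pytest.approx(319.0, abs=3.0)
        assert transitions[1].temperature_range[0] == pytest.approx(325.0, abs=3.0)


class TestInactivation:
    def test_exact_exponential_self_fit(self):
        t = np.linspace(0.0, 20.0, 15)
        trace = ProbeTrace(t, np.exp(-0.2 * t), hold_temperature=317.15)
        series = fit_inactivation([trace])
        assert series.table.k_per_min[0] == pytest.approx(0.2, abs=1e-10)

    def test_noisy_rates_within_ten_percent(self, probe_set):
        series = fit_inactivation(probe_set["inactivation"])
        for rec, truth in zip(series.table.itertuples(),
                              probe_set["truth"]["inactivation"]):
            assert rec.k_per_min == pytest.approx(truth["k"], rel=0.10)

    def test_pooled_traces_consistent_with_single_fit(self):
        rng = np.random.default_rng(8)
        t = np.linspace(0.0, 15.0, 12)
        k = 0.15
        y1 = np.exp(-k * t) + 0.02 * rng.standard_normal(t.size)
        y2 = np.exp(-k * t) + 0.02 * rng.standard_normal(t.size)
        separate = fit_inactivation([ProbeTrace(t, y1, hold_temperature=316.15),
                                     ProbeTrace(t, y2, hold_temperature=316.15)])
        t_cat = np.concatenate([t, t + 1e-9])
        order = np.argsort(t_cat)
        pooled = fit_inactivation([
            ProbeTrace(t_cat[order], np.concatenate([y1, y2])[order],
                       hold_temperature=316.15)])
        k_sep = separate.table.k_per_min.mean()
        k_pool = pooled.table.k_per_min[0]
        ci = separate.table.k_ci_half.max()
        assert abs(k_pool - k_sep) < ci

    def test_non_decaying_trace_at_boundary(self):
        t = np.linspace(0.0, 10.0, 8)
        series = fit_inactivation([ProbeTrace(t, np.full(8, 1.0),
                                              hold_temperature=317.15)])
        assert series.table.k_per_min[0] == pytest.approx(0.0, abs=1e-4)
        assert series.table.at_boundary[0]


class TestOverlayWithDsc:
    def test_inactivation_tracks_stage_one_of_motor_domain(self, probe_set, s1_model):
        series = fit_inactivation(probe_set["inactivation"])
        table = overlay_with_dsc(series, s1_model)
        by = table.groupby("transition")["log10_ratio"].apply(
            lambda s: np.mean(np.abs(s)))
        assert by["transition 2"] < 0.1          # matches the generating law
        assert by["transition 1"] > 3.0 * by["transition 2"]

    def test_a_norm_contained_in_two_stage_window(self, probe_set, fluor_scan, s1_model):
        _, A_norm = compute_parameter_a(fluor_scan)
        report = overlay_with_dsc((fluor_scan.temperature, A_norm), s1_model)
        assert report["contained"] is True
        assert report["best_match"] == "two-stage domain (combined)"

    def test_empty_series_empty_report(self, s1_model):
        import pandas as pd

        table = overlay_with_dsc(InactivationSeries(pd.DataFrame(
            columns=["temperature_K", "k_per_min"])), s1_model)
        assert len(table) == 0
        report = overlay_with_dsc((np.array([]), np.array([])), s1_model)
        assert report["contained"] is None
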