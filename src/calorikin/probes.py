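"""Fluorescence and enzyme-inactivation probes of thermal denaturation.

Two independent probes localise which calorimetric transition belongs to
which structural part of the protein:

* Intrinsic tryptophan fluorescence.  The spectral parameter
  A = I320 / I365 tracks the emission-spectrum position; its normalised
  form A_norm = (A - A_min)/(A_max - A_min) rises across the structural
  transition(s) of the tryptophan-bearing region.  The parametric
  (phase) plot of I365 against I320, with temperature as the running
  parameter, separates trivial thermal quenching (linear segments
  extrapolating through the origin) from structural transitions
  (segments whose extrapolated intercept excludes zero).
* Residual enzymatic activity after isothermal holds decays
  mono-exponentially for a first-order inactivation step; its rate
  constants across temperatures are compared with the Arrhenius rates of
  each calorimetric transition to find the matching one.

Phase-plot segmentation here is an ordered change-point fit with a
per-segment intercept test (in practice such segments are usually
identified by eye); the plot is deliberately reported as ranges and
classifications, not kinetic parameters, because quantitative fitting
of parametric dependences is too error-sensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .curves import CurveValidationError, ProbeTrace
from .kinetics import (
    DomainModel,
    OneStageDomain,
    arrhenius_rate,
    native_fraction_scan,
    two_stage_state_fractions,
)

__all__ = [
    "FluorescenceScan",
    "InactivationSeries",
    "compute_parameter_a",
    "parametric_plot",
    "fit_inactivation",
    "overlay_with_dsc",
]


@dataclass(frozen=True)
class FluorescenceScan:
    """Temperature scan of the two fluorescence channels."""

    temperature: np.ndarray
    I320: np.ndarray
    I365: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature, dtype=float)
        a = np.asarray(self.I320, dtype=float)
        b = np.asarray(self.I365, dtype=float)
        for name, arr in (("temperature", T), ("I320", a), ("I365", b)):
            object.__setattr__(self, name, arr)
        if not (a.shape == b.shape == T.shape):
            raise CurveValidationError("both channels must match the temperature grid")
        if np.any(np.diff(T) <= 0):
            raise CurveValidationError("temperature must be strictly increasing")

    @classmethod
    def from_trace(cls, trace: ProbeTrace) -> "FluorescenceScan":
        if trace.ordinate2 is None:
            raise CurveValidationError("fluorescence trace needs both channels")
        return cls(trace.abscissa, trace.ordinate, trace.ordinate2)


@dataclass(frozen=True)
class PhaseSegment:
    """One linear stretch of the (I320, I365) phase plot."""

    temperature_range: tuple[float, float]
    slope: float
    intercept: float
    intercept_ci: tuple[float, float]
    through_origin: bool  # True: pure quenching of one state


@dataclass(frozen=True)
class InactivationSeries:
    """First-order inactivation rate constants per hold temperature."""

    table: pd.DataFrame  # temperature_K, k_per_min, k_ci_half, residual_sd


def compute_parameter_a(scan: FluorescenceScan) -> tuple[np.ndarray, np.ndarray]:
    """Spectral parameter A = I320/I365 and its normalised form.

    A_norm endpoints attain 0 and 1 exactly at the grid's extremes of A.
    A flat scan (A_max = A_min) has no defined normalisation and raises.
    """
    if np.any(scan.I320 <= 0) or np.any(scan.I365 <= 0):
        raise CurveValidationError("channel intensities must be positive")
    A = scan.I320 / scan.I365
    A_min, A_max = float(np.min(A)), float(np.max(A))
    if A_max - A_min <= 1e-12 * max(abs(A_max), 1.0):
        raise CurveValidationError("A is constant; normalisation undefined")
    return A, (A - A_min) / (A_max - A_min)


def _segment_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    fit = stats.linregress(x, y)
    dof = x.size - 2
    if dof > 0 and fit.intercept_stderr and math.isfinite(fit.intercept_stderr):
        half = stats.t.ppf(0.975, dof) * fit.intercept_stderr
    else:
        half = math.inf
    return float(fit.slope), float(fit.intercept), (float(fit.intercept - half),
                                                    float(fit.intercept + half))


def parametric_plot(scan: FluorescenceScan, *, min_points: int = 4,
                    slope_fraction: float = 0.1,
                    origin_tolerance: float = 0.02) -> list[PhaseSegment]:
    """Piecewise-linear segmentation of the (I320, I365) phase plot.

    Segment boundaries are change points of the spectral parameter
    A = I320/I365 along the temperature axis: stretches where |dA/dT|
    stays below ``slope_fraction`` of its maximum are state plateaus
    (pure thermal quenching — their phase-plot line extrapolates through
    the origin), stretches above it are structural transitions; a
    transition stretch containing two separated peaks of |dA/dT| is
    split at the valley between them (two sequential transitions).
    Runs shorter than ``min_points`` are merged into their neighbour.

    Each segment's (I320, I365) points are fit with a straight line and
    classified ``through_origin`` when the extrapolated intercept is
    compatible with zero (95% CI, padded by ``origin_tolerance`` of the
    intensity scale).
    """
    x, y, T = scan.I320, scan.I365, scan.temperature
    n = x.size
    if n < 20:
        raise CurveValidationError("need at least 20 scan points")

    A = x / y
    dA = np.abs(np.gradient(A, T))
    # absolute floor: a scan whose A never moves appreciably is one state
    floor = 1e-6 * float(np.mean(A)) / float(T[-1] - T[0]) * T.size
    thr = max(slope_fraction * float(np.max(dA)), floor)
    active = dA > thr

    # contiguous runs of constant state
    breaks = [0]
    for i in range(1, n):
        if active[i] != active[i - 1]:
            breaks.append(i)
    breaks.append(n)

    # split transition runs with two interior derivative peaks
    from scipy.signal import argrelmax

    refined = [0]
    for i, j in zip(breaks[:-1], breaks[1:]):
        if active[i] and j - i >= 2 * min_points:
            seg = dA[i:j]
            peaks = [p for p in argrelmax(seg, order=2)[0]
                     if seg[p] > 2.0 * thr]
            if len(peaks) >= 2:
                valley = peaks[0] + int(np.argmin(seg[peaks[0]:peaks[-1] + 1]))
                if seg[valley] < 0.8 * min(seg[peaks[0]], seg[peaks[-1]]):
                    refined.append(i + valley)
        refined.append(j)
    breaks = sorted(set(refined))

    # merge short runs into the neighbour
    merged = [breaks[0]]
    for b in breaks[1:-1]:
        if b - merged[-1] >= min_points:
            merged.append(b)
    merged.append(breaks[-1])
    if merged[-1] - merged[-2] < min_points and len(merged) > 2:
        merged.pop(-2)
    breaks = merged

    segments: list[PhaseSegment] = []
    scale = float(np.max(np.abs(y)))
    for i, j in zip(breaks[:-1], breaks[1:]):
        slope, intercept, ci = _segment_fit(x[i:j], y[i:j])
        lo, hi = ci
        tol = origin_tolerance * scale
        through = (lo - tol) <= 0.0 <= (hi + tol)
        segments.append(PhaseSegment((float(T[i]), float(T[j - 1])),
                                     slope, intercept, ci, through))
    return segments


def fit_inactivation(traces, *, free_amplitude: bool = False) -> InactivationSeries:
    """Mono-exponential decay fits of residual-activity time courses.

    Each trace is ``activity(t) = a exp(-k t)`` with the amplitude fixed
    at 1 by default (activities are pre-normalised).  ``k`` is
    constrained non-negative; a non-decaying trace is reported at the
    k = 0 boundary.  The 95% CI comes from the Jacobian of the
    least-squares fit.
    """
    rows = []
    for trace in traces:
        t = trace.abscissa
        y = trace.ordinate
        if t.size < 4:
            raise ValueError("each trace needs at least 4 points")

        if free_amplitude:
            def resid(theta):
                a, k = theta
                return a * np.exp(-k * t) - y
            x0 = [max(y[0], 1e-6), 0.1]
            bounds = ([1e-9, 0.0], [np.inf, np.inf])
        else:
            def resid(theta):
                (k,) = theta
                return np.exp(-k * t) - y
            x0 = [0.1]
            bounds = ([0.0], [np.inf])

        res = optimize.least_squares(resid, x0=x0, bounds=bounds,
                                     method="trf", xtol=1e-14, ftol=1e-14)
        k = float(res.x[-1])
        r = res.fun
        dof = max(t.size - res.x.size, 1)
        s2 = float(np.dot(r, r)) / dof
        try:
            JTJ = res.jac.T @ res.jac
            var = s2 * np.linalg.inv(JTJ)[-1, -1]
            ci = 1.96 * math.sqrt(max(var, 0.0))
        except np.linalg.LinAlgError:
            ci = math.nan
        rows.append({"temperature_K": trace.hold_temperature,
                     "k_per_min": k, "k_ci_half": ci,
                     "residual_sd": float(np.std(r)),
                     # no measurable decay over the observed span
                     "at_boundary": bool(k * t[-1] < 1e-3)})
    return InactivationSeries(pd.DataFrame(rows))


def _conversion_windows(model: DomainModel, T: np.ndarray, nu: float,
                        lo: float = 0.05, hi: float = 0.95) -> dict[str, tuple[float, float]]:
    """5-95% conversion window of every transition on the grid T."""
    windows: dict[str, tuple[float, float]] = {}
    idx = 0
    for d in model.domains:
        idx += 1
        if isinstance(d, OneStageDomain):
            conv = 1.0 - native_fraction_scan(d.kinetics, T, nu)
            windows[f"transition {idx}"] = _crossings(T, conv, lo, hi)
        else:
            xN, _, xD = two_stage_state_fractions(d, T, nu)
            windows[f"transition {idx}"] = _crossings(T, 1.0 - xN / max(d.x_N0, 1e-300), lo, hi)
            idx += 1
            windows[f"transition {idx}"] = _crossings(T, xD / max(d.x_N0 + d.x_I0, 1e-300), lo, hi)
    return windows


def _crossings(T: np.ndarray, conv: np.ndarray, lo: float, hi: float) -> tuple[float, float]:
    def cross(level):
        j = int(np.argmax(conv >= level))
        if conv[j] < level:
            return float(T[-1])
        if j == 0:
            return float(T[0])
        f = (level - conv[j - 1]) / (conv[j] - conv[j - 1])
        return float(T[j - 1] + f * (T[j] - T[j - 1]))
    return cross(lo), cross(hi)


def overlay_with_dsc(series, model: DomainModel, *, nu: float = 1.0):
    """Compare a probe read-out with the calorimetric domain model.

    * ``InactivationSeries`` input: returns a table with, per hold
      temperature, the log10 ratio of the measured inactivation rate to
      the Arrhenius rate of each transition; the matching transition has
      log-ratios near zero.
    * ``(T, A_norm)`` tuple input: returns whether the 5-95% rise window
      of A_norm lies inside the union of the two-stage domain's
      transition windows (1 K slack), plus the RMS mismatch between
      A_norm and each transition's conversion curve and their
      enthalpy-weighted combination — the probe is assigned to whatever
      it tracks best.

    An empty series yields an empty report.
    """
    params = model.transition_parameters()
    if isinstance(series, InactivationSeries):
        rows = []
        for _, rec in series.table.iterrows():
            T = rec["temperature_K"]
            k_obs = rec["k_per_min"]
            for i, p in enumerate(params, start=1):
                k_model = arrhenius_rate(p, T)
                rows.append({"temperature_K": T, "transition": f"transition {i}",
                             "k_observed": k_obs, "k_model": k_model,
                             "log10_ratio": (math.log10(k_obs / k_model)
                                             if k_obs > 0 else -math.inf)})
        return pd.DataFrame(rows)

    T, a_norm = series
    T = np.asarray(T, dtype=float)
    a_norm = np.asarray(a_norm, dtype=float)
    if T.size == 0:
        return {"rise_window_K": None, "contained": None, "windows_K": {},
                "rms_mismatch": {}, "best_match": None}
    rise = _crossings(T, a_norm, 0.05, 0.95)
    windows = _conversion_windows(model, T, nu)

    # conversion curves per transition on the probe's own grid
    conversions: dict[str, np.ndarray] = {}
    weights: dict[str, float] = {}
    idx = 0
    multi_names: list[str] = []
    for d in model.domains:
        idx += 1
        if isinstance(d, OneStageDomain):
            conversions[f"transition {idx}"] = 1.0 - native_fraction_scan(d.kinetics, T, nu)
            weights[f"transition {idx}"] = d.dH
        else:
            xN, _, xD = two_stage_state_fractions(d, T, nu)
            conversions[f"transition {idx}"] = 1.0 - xN / max(d.x_N0, 1e-300)
            weights[f"transition {idx}"] = d.dH1
            multi_names.append(f"transition {idx}")
            idx += 1
            conversions[f"transition {idx}"] = xD / max(d.x_N0 + d.x_I0, 1e-300)
            weights[f"transition {idx}"] = d.dH2
            multi_names.append(f"transition {idx}")

    rms = {name: float(np.sqrt(np.mean((a_norm - conv) ** 2)))
           for name, conv in conversions.items()}
    if multi_names:
        wsum = sum(weights[nm] for nm in multi_names)
        combo = sum(weights[nm] * conversions[nm] for nm in multi_names) / wsum
        rms["two-stage domain (combined)"] = float(np.sqrt(np.mean((a_norm - combo) ** 2)))

    contained = None
    if multi_names:
        lo = min(windows[nm][0] for nm in multi_names)
        hi = max(windows[nm][1] for nm in multi_names)
        contained = bool((rise[0] >= lo - 1.0) and (rise[1] <= hi + 1.0))
    best = min(rms, key=rms.get) if rms else None
    return {"rise_window_K": rise, "contained": contained, "windows_K": windows,
            "rms_mismatch": rms, "best_match": best}
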