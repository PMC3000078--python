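"""Heat-induced aggregation kinetics from DLS radius traces.

During an isothermal hold, the mean hydrodynamic radius of growing
protein aggregates follows, after a lag t_0,

    R_h(t) = R_h0 * exp[(ln 2 / t_2R) (t - t_0)],    t > t_0,

so log R_h is flat until t_0 and linear afterwards with slope
ln 2 / t_2R.  The doubling time t_2R characterises the aggregation rate;
the lag t_0 reflects nucleation and is irreproducible between runs, so
it is treated as a nuisance parameter and estimated jointly as a
change point.  Concentration independence of t_2R is the signature that
a first-order (denaturation) step limits the growth.

Across hold temperatures, the growth rate k_agg = ln 2 / t_2R(T) is fit
with the Arrhenius law in the (E_a, T*) parameterisation — the ln 2
convention keeps t_2R(T*) = ln 2 min consistent with the half-life
t_0.5 = ln 2 / k, which is how the doubling time is compared with the
denaturation kinetics of candidate rate-limiting transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .curves import ProbeTrace
from .kinetics import (
    GAS_CONSTANT,
    DomainModel,
    KineticParameters,
    OneStageDomain,
    TwoStageDomain,
    arrhenius_rate,
    half_life,
    native_fraction_scan,
    two_stage_state_fractions,
)

__all__ = [
    "AggregationFit",
    "AggregationArrhenius",
    "fit_growth",
    "fit_aggregation_arrhenius",
    "compare_with_denaturation",
    "scan_growth_overlay",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class AggregationFit:
    """Exponential-growth fit of one isothermal R_h trace."""

    t_0: float            # lag before growth [min]
    R_h0: float           # radius at t_0 [nm]
    t_2R: float           # doubling time [min]
    hold_temperature: float | None
    t_2R_ci: float        # 95% half-width on t_2R [min]
    growing: bool = True  # False when no growth was detected

    @property
    def rate(self) -> float:
        """Growth rate k_agg = ln 2 / t_2R [1/min]."""
        return LN2 / self.t_2R


@dataclass(frozen=True)
class AggregationArrhenius:
    """Arrhenius parameters of the radius-growth process."""

    E_a: float
    T_star: float
    table: pd.DataFrame   # per-temperature t_2R and k_agg

    @property
    def kinetics(self) -> KineticParameters:
        return KineticParameters(self.E_a, self.T_star)


def _changepoint_sse(t: np.ndarray, logr: np.ndarray, i: int) -> tuple[float, float, float, float]:
    """SSE of the flat-then-linear model with the break after index i.

    Continuity at the break: level a before t_b, a + s (t - t_b) after,
    with t_b = t[i] (growth starts at the first growing sample).
    """
    tb = t[i]
    pre = logr[: i + 1]
    post_t = t[i:] - tb
    post_r = logr[i:]
    # joint LS for (a, s): a = mean over pre and post intercept; solve 2x2
    n_pre = pre.size
    S1 = post_t.sum()
    S2 = (post_t ** 2).sum()
    y_pre = pre.sum()
    y_post = post_r.sum()
    yt = (post_r * post_t).sum()
    n_post = post_r.size
    A = np.array([[n_pre + n_post, S1], [S1, S2]])
    b = np.array([y_pre + y_post, yt])
    try:
        a, s = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return math.inf, 0.0, 0.0, tb
    sse = float(((pre - a) ** 2).sum() + ((post_r - a - s * post_t) ** 2).sum())
    return sse, float(a), float(s), float(tb)


def fit_growth(trace: ProbeTrace, *, min_post_points: int = 6) -> AggregationFit:
    """Fit the lagged exponential to one isothermal radius trace.

    The lag is estimated jointly by a change-point search on log R_h
    (flat before, linear after, continuous at the break), then
    (t_0, R_h0, t_2R) are polished by nonlinear least squares on the
    full piecewise model.  A non-positive post-lag slope flags a
    non-aggregating trace.
    """
    t = trace.abscissa
    r = trace.ordinate
    if np.any(r <= 0):
        raise ValueError("radii must be positive")
    if t.size < min_post_points + 1:
        raise ValueError(f"need at least {min_post_points + 1} points")
    logr = np.log(r)

    best = None
    for i in range(0, t.size - min_post_points):
        sse, a, s, tb = _changepoint_sse(t, logr, i)
        if best is None or sse < best[0]:
            best = (sse, a, s, tb)
    _, a, s, tb = best

    if s <= 0:
        return AggregationFit(float(tb), float(math.exp(a)), math.inf,
                              trace.hold_temperature, math.nan, growing=False)

    def model(theta):
        t0, log_r0, slope = theta
        pred = np.where(t <= t0, log_r0, log_r0 + slope * (t - t0))
        return pred - logr

    res = optimize.least_squares(model, x0=[tb, a, s], method="trf",
                                 xtol=1e-14, ftol=1e-14)
    t0, log_r0, slope = res.x
    if slope <= 0:
        return AggregationFit(float(t0), float(math.exp(log_r0)), math.inf,
                              trace.hold_temperature, math.nan, growing=False)
    t2R = LN2 / slope
    # 95% CI on the slope from the post-lag linear stretch, mapped to t_2R
    post = t > t0
    if post.sum() >= 3:
        fit = stats.linregress(t[post], logr[post])
        half = 1.96 * fit.stderr if fit.stderr and math.isfinite(fit.stderr) else 0.0
        ci = LN2 * half / slope ** 2
    else:
        ci = math.nan
    return AggregationFit(float(t0), float(math.exp(log_r0)), float(t2R),
                          trace.hold_temperature, float(ci))


def fit_aggregation_arrhenius(fits) -> AggregationArrhenius:
    """Arrhenius fit of growth rates across hold temperatures.

    Converts each doubling time to k_agg = ln 2 / t_2R and fits
    ln k = (E_a/R)(1/T* - 1/T) by least squares of ln k against 1/T;
    needs >= 3 growing fits spanning >= 4 K.
    """
    usable = [f for f in fits if f.growing and f.hold_temperature is not None]
    temps = np.array([f.hold_temperature for f in usable], dtype=float)
    if len(usable) < 3:
        raise ValueError("need at least 3 usable temperatures")
    if np.ptp(temps) < 4.0:
        raise ValueError("hold temperatures must span at least 4 K")
    t2R = np.array([f.t_2R for f in usable])
    k = LN2 / t2R
    # ln k = -(E_a/R)/T + (E_a/R)/T*
    fit = stats.linregress(1.0 / temps, np.log(k))
    E_a = -fit.slope * GAS_CONSTANT
    if E_a <= 0:
        raise ValueError("growth rates decrease with temperature; no Arrhenius fit")
    T_star = -fit.slope / fit.intercept
    table = pd.DataFrame({"temperature_K": temps, "t_2R_min": t2R, "k_agg_per_min": k})
    return AggregationArrhenius(float(E_a), float(T_star),
                                table.sort_values("temperature_K").reset_index(drop=True))


def _candidate_transitions(model: DomainModel) -> list[tuple[str, KineticParameters]]:
    out = []
    for i, d in enumerate(model.domains, start=1):
        if isinstance(d, OneStageDomain):
            out.append((f"domain {i}", d.kinetics))
        else:
            out.append((f"domain {i} stage 1", d.stage1))
            out.append((f"domain {i} stage 2", d.stage2))
    return out


def compare_with_denaturation(agg: AggregationArrhenius, model: DomainModel) -> pd.DataFrame:
    """Tabulate t_2R against the half-life of every candidate transition.

    One row per (temperature, transition) with the relative deviation
    |t_0.5 - t_2R| / t_2R; the transition with near-zero deviation across
    temperatures is the rate-limiting denaturation step.
    """
    rows = []
    for _, rec in agg.table.iterrows():
        T = float(rec["temperature_K"])
        t2R = float(rec["t_2R_min"])
        for name, p in _candidate_transitions(model):
            t05 = half_life(p, T)
            rows.append({"temperature_K": T, "transition": name,
                         "t_2R_min": t2R, "t_05_min": t05,
                         "relative_deviation": abs(t05 - t2R) / t2R})
    return pd.DataFrame(rows)


def scan_growth_overlay(trace: ProbeTrace, model: DomainModel, nu: float,
                        *, radius_threshold: float = 100.0) -> dict:
    """Temperature offset between R_h onset and each transition midpoint.

    ``trace`` is a constant-rate-heating R_h(T) record.  For each
    transition the fraction-of-conversion curve is computed on the
    trace's temperature axis (for a two-stage domain, stage 1 conversion
    is 1 - x_N and stage 2 conversion is x_D); the report gives the
    onset temperature (first crossing of ``radius_threshold``), each
    conversion midpoint, and the delays onset - midpoint [K].
    """
    T = trace.abscissa
    r = trace.ordinate
    above = r >= radius_threshold
    if not above.any():
        raise ValueError("radius never reaches the onset threshold")
    i = int(np.argmax(above))
    if i == 0:
        T_onset = float(T[0])
    else:
        # linear interpolation to the crossing
        f = (radius_threshold - r[i - 1]) / (r[i] - r[i - 1])
        T_onset = float(T[i - 1] + f * (T[i] - T[i - 1]))

    conversions: dict[str, np.ndarray] = {}
    idx = 0
    for d in model.domains:
        idx += 1
        if isinstance(d, OneStageDomain):
            x = native_fraction_scan(d.kinetics, T, nu)
            conversions[f"transition {idx}"] = 1.0 - x
        else:
            xN, _, xD = two_stage_state_fractions(d, T, nu)
            total = d.x_N0 + d.x_I0
            conversions[f"transition {idx}"] = 1.0 - xN / max(d.x_N0, 1e-300)
            idx += 1
            conversions[f"transition {idx}"] = xD / max(total, 1e-300)

    midpoints = {}
    delays = {}
    for name, conv in conversions.items():
        if conv[-1] < 0.5:
            midpoints[name] = math.nan
            delays[name] = math.nan
            continue
        j = int(np.argmax(conv >= 0.5))
        if j == 0:
            Tm = float(T[0])
        else:
            f = (0.5 - conv[j - 1]) / (conv[j] - conv[j - 1])
            Tm = float(T[j - 1] + f * (T[j] - T[j - 1]))
        midpoints[name] = Tm
        delays[name] = T_onset - Tm
    return {"onset_temperature_K": T_onset, "midpoints_K": midpoints,
            "delays_K": delays, "conversions": conversions}
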