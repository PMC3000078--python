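r"""W(T) diagnostic and recursive transition peeling.

For a single one-stage irreversible transition the rate constant can be
read directly off the excess-heat-capacity curve,

    k(T) = nu C_p^ex(T) / \int_T^end C_p^ex dT,

and the function

    W(T) = T (ln nu + ln C_p^ex(T) - ln \int_T^end C_p^ex dT)

is linear in T exactly when the one-stage model holds, with

    W(T) = (E_a / (R T*)) T - E_a / R,

so E_a = -R * intercept and T* = E_a / (R * slope).  A multi-transition
thermogram bends W(T); but at the high-temperature end only the most
thermostable transition survives, so the tail of W is linear and yields
that transition's Arrhenius pair.  Its enthalpy follows from a least
squares fit of C_p^ex against k x / nu in the same window; subtracting
the simulated transition and repeating peels the thermogram apart
transition by transition.  The peeled parameters are a null
approximation only — they seed annealing design and the final joint
fit — but the apparent transition count is determined reliably.

Thresholds for "the tail is linear" are this package's own: the longest
high-temperature window (>= 15 points) whose straight-line residual SD
stays below a noise-scaled threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.integrate import trapezoid

from .curves import ExcessCurve
from .kinetics import (
    GAS_CONSTANT,
    KineticParameters,
    OneStageDomain,
    arrhenius_rate,
    native_fraction_scan,
    simulate_one_stage,
)

__all__ = [
    "WTCurve",
    "PeelingResult",
    "rate_from_curve",
    "compute_wt",
    "peel_transitions",
    "check_one_stage",
]


@dataclass(frozen=True)
class WTCurve:
    """The W(T) diagnostic with its linear-segment fit."""

    temperature: np.ndarray      # unmasked grid points only
    W: np.ndarray
    window: tuple[float, float]  # [K, K] interval used for the linear fit
    slope: float
    intercept: float
    E_a: float                   # -R * intercept [kJ/mol]
    T_star: float                # E_a / (R * slope) [K]
    residual_sd: float

    @property
    def kinetics(self) -> KineticParameters:
        return KineticParameters(self.E_a, self.T_star)


@dataclass(frozen=True)
class OneStageFitReport:
    """Full-window single-transition fit with quality metrics."""

    E_a: float
    T_star: float
    dH: float
    residual_sd: float
    peak_height: float

    @property
    def kinetics(self) -> KineticParameters:
        return KineticParameters(self.E_a, self.T_star)


@dataclass(frozen=True)
class PeeledTransition:
    """One extracted transition (null approximation)."""

    E_a: float
    T_star: float
    dH: float
    window: tuple[float, float]

    @property
    def kinetics(self) -> KineticParameters:
        return KineticParameters(self.E_a, self.T_star)


@dataclass(frozen=True)
class PeelingResult:
    """Transitions peeled from a thermogram, most thermostable first.

    Parameters are null approximations; ``count`` is the apparent number
    of one-stage transitions.  ``complete`` is False when peeling stopped
    because no linear tail window could be found while significant area
    remained.
    """

    transitions: tuple = ()
    residuals: tuple = ()        # residual ExcessCurve after each peel
    total_enthalpy: float = 0.0
    complete: bool = True

    @property
    def count(self) -> int:
        return len(self.transitions)


def _tail_mask(ex: ExcessCurve, floor: float) -> np.ndarray:
    """Points where C_p^ex > 0 and the remaining tail area is above the
    positivity floor (fraction of total area)."""
    remaining = ex.remaining_heat()
    total = abs(ex.total_enthalpy)
    return (ex.excess_heat_capacity > 0) & (remaining > floor * total)


def rate_from_curve(ex: ExcessCurve, nu: float, *, floor: float = 0.01):
    """Rate constant k(T) read off a one-transition excess curve.

    Returns ``(T, k)`` restricted to the unmasked window; points where
    the remaining area drops below ``floor`` of the total (or C_p^ex is
    non-positive) are masked, never extrapolated.
    """
    mask = _tail_mask(ex, floor)
    if not mask.any():
        raise ValueError("no usable points above the positivity floor")
    remaining = ex.remaining_heat()
    k = nu * ex.excess_heat_capacity[mask] / remaining[mask]
    return ex.temperature[mask], k


def compute_wt(ex: ExcessCurve, nu: float, *, floor: float = 0.01,
               window: tuple[float, float] | None = None,
               min_points: int = 15, sd_factor: float = 2.0) -> WTCurve:
    """Compute W(T) and fit its (longest) linear high-temperature segment.

    If ``window`` is given the linear fit uses exactly that temperature
    interval; otherwise the longest tail window passing the residual
    criterion is used (falling back to the full unmasked range when no
    window qualifies).
    """
    T, k = rate_from_curve(ex, nu, floor=floor)
    W = T * np.log(k)
    if window is None:
        lo_idx = _longest_linear_tail(T, W, min_points, sd_factor)
        window = (float(T[lo_idx]), float(T[-1]))
    sel = (T >= window[0] - 1e-12) & (T <= window[1] + 1e-12)
    if sel.sum() < 3:
        raise ValueError("linear-fit window contains fewer than 3 points")
    fit = stats.linregress(T[sel], W[sel])
    E_a = -GAS_CONSTANT * fit.intercept
    if E_a <= 0:
        raise ValueError("W(T) fit gives non-positive activation energy; "
                         "curve is not one-stage in the window")
    T_star = E_a / (GAS_CONSTANT * fit.slope)
    resid = W[sel] - (fit.slope * T[sel] + fit.intercept)
    return WTCurve(T, W, window, float(fit.slope), float(fit.intercept),
                   float(E_a), float(T_star), float(np.std(resid)))


def _local_noise_sd(W: np.ndarray) -> float:
    """Noise scale of W from second differences (insensitive to smooth
    curvature)."""
    if W.size < 3:
        return 0.0
    d2 = np.diff(W, 2)
    # median absolute deviation -> SD, / sqrt(6) for the 2nd-difference kernel
    return float(1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0))


def _longest_linear_tail(T: np.ndarray, W: np.ndarray,
                         min_points: int, sd_factor: float) -> int:
    """Index of the start of the longest linear tail window of W(T).

    Extends the window downward from the high-temperature end while the
    straight-line residual SD stays below ``sd_factor`` times a local
    noise estimate (with a small absolute floor for noiseless data).
    """
    n = T.size
    if n < min_points:
        raise ValueError(f"need at least {min_points} points, got {n}")
    noise = _local_noise_sd(W[-min(n, 4 * min_points):])
    span = float(np.ptp(W)) if n else 1.0
    tol = max(sd_factor * noise * np.sqrt(max(1.0, n / 10.0)), 1e-6 * max(span, 1.0))
    best = n - min_points
    for lo in range(n - min_points, -1, -1):
        t, w = T[lo:], W[lo:]
        fit = stats.linregress(t, w)
        sd = float(np.std(w - (fit.slope * t + fit.intercept)))
        if sd <= tol:
            best = lo
        else:
            break
    return best


def _fit_dH(ex: ExcessCurve, nu: float, p: KineticParameters, sel: np.ndarray) -> float:
    """Least-squares enthalpy: C_p^ex vs k x / nu over the window."""
    x = native_fraction_scan(p, ex.temperature, nu)
    phi = arrhenius_rate(p, ex.temperature) * x / nu
    num = float(np.dot(ex.excess_heat_capacity[sel], phi[sel]))
    den = float(np.dot(phi[sel], phi[sel]))
    if den <= 0:
        raise ValueError("degenerate design in enthalpy fit")
    return num / den


def _refine_window(ex: ExcessCurve, nu: float, E_a: float, T_star: float,
                   dH: float, sel: np.ndarray) -> tuple[float, float, float]:
    """Local re-optimisation of (E_a, T*, dH) on the window where they
    were determined, to curb error accumulation across peels."""
    T = ex.temperature
    y = ex.excess_heat_capacity[sel]

    def resid(theta):
        ea, ts, dh = theta
        p = KineticParameters(ea, ts)
        x = native_fraction_scan(p, T, nu)
        model = dh * arrhenius_rate(p, T) * x / nu
        return model[sel] - y

    lb = np.array([50.0, 280.0, 1e-6])
    ub = np.array([1500.0, 400.0, 1e5])
    x0 = np.clip([E_a, T_star, dH], lb * (1 + 1e-9), ub * (1 - 1e-9))
    res = optimize.least_squares(resid, x0=x0, bounds=(lb, ub),
                                 method="trf", xtol=1e-12, ftol=1e-12)
    return tuple(float(v) for v in res.x)


def _polish_components(ex: ExcessCurve, nu: float, comps: list[np.ndarray]) -> list[np.ndarray]:
    """Joint least squares of all one-stage components on the full curve."""
    T = ex.temperature
    y = ex.excess_heat_capacity
    n = len(comps)

    def model(theta):
        out = np.zeros_like(T)
        for j in range(n):
            ea, ts, dh = theta[3 * j: 3 * j + 3]
            p = KineticParameters(ea, ts)
            out += dh * arrhenius_rate(p, T) * native_fraction_scan(p, T, nu) / nu
        return out

    lb = np.tile([50.0, 280.0, 1e-6], n)
    ub = np.tile([1500.0, 400.0, 1e5], n)
    x0 = np.clip(np.concatenate(comps), lb, ub)
    res = optimize.least_squares(lambda th: model(th) - y, x0,
                                 bounds=(lb, ub), method="trf", xtol=1e-12)
    return [res.x[3 * j: 3 * j + 3].copy() for j in range(n)]


def peel_transitions(ex: ExcessCurve, nu: float, *, floor: float = 0.01,
                     stop_fraction: float = 0.03, min_points: int = 15,
                     sd_factor: float = 2.0, max_transitions: int = 10,
                     refine: bool = True, polish: bool = True,
                     merge_gap: float = 2.0) -> PeelingResult:
    """Recursively peel apparent one-stage transitions off a thermogram.

    Each cycle: locate the longest linear high-temperature window of
    W(T); read (E_a, T*) from its line; fit dH by least squares of
    C_p^ex against k x / nu there; locally re-optimise the triple on the
    window; subtract the simulated one-stage curve; repeat on the
    residual until the remaining area falls below ``stop_fraction`` of
    the original total.

    With ``polish`` (default) the greedy extraction is followed by a
    joint least-squares polish of all components on the full curve,
    pruning of components whose enthalpy falls below ``stop_fraction``
    of the total, and merging of components whose T* values sit closer
    than ``merge_gap`` (default 2 K — the annealing method cannot
    resolve transitions closer than that, so sub-resolution pairs are
    one apparent transition).  Returns transitions from most to least
    thermostable.
    """
    total = ex.total_enthalpy
    if total <= 0:
        raise ValueError("excess curve has non-positive total area")
    current = ex
    transitions: list[PeeledTransition] = []
    residuals: list[ExcessCurve] = []
    complete = True
    for _ in range(max_transitions):
        area = trapezoid(current.excess_heat_capacity, current.temperature)
        if abs(area) < stop_fraction * total:
            break
        try:
            wt = compute_wt(current, nu, floor=floor,
                            min_points=min_points, sd_factor=sd_factor)
        except ValueError:
            complete = False
            break
        sel = ((current.temperature >= wt.window[0] - 1e-12)
               & (current.temperature <= wt.window[1] + 1e-12)
               & (current.excess_heat_capacity > 0))
        try:
            dH = _fit_dH(current, nu, wt.kinetics, sel)
            E_a, T_star, dH = wt.E_a, wt.T_star, max(dH, 1e-6)
            if refine:
                E_a, T_star, dH = _refine_window(current, nu, E_a, T_star, dH, sel)
        except ValueError:
            complete = False
            break
        transitions.append(PeeledTransition(E_a, T_star, dH, wt.window))
        peel = simulate_one_stage(OneStageDomain(KineticParameters(E_a, T_star), dH),
                                  current.temperature, nu)
        current = ExcessCurve(current.temperature,
                              current.excess_heat_capacity - peel.excess_heat_capacity,
                              heating_rate=nu)
        residuals.append(current)
    else:
        complete = False

    if polish and transitions:
        comps = [np.array([t.E_a, t.T_star, t.dH]) for t in transitions]
        comps = _polish_components(ex, nu, comps)
        kept = [c for c in comps if c[2] >= stop_fraction * total]
        if kept and len(kept) < len(comps):
            comps = _polish_components(ex, nu, kept)
        # merge apparent transitions closer than the resolving limit
        while True:
            comps.sort(key=lambda c: -c[1])
            for i in range(len(comps) - 1):
                if comps[i][1] - comps[i + 1][1] < merge_gap:
                    a, b = comps[i], comps[i + 1]
                    w = a[2] + b[2]
                    merged = np.array([(a[0] * a[2] + b[0] * b[2]) / w,
                                       (a[1] * a[2] + b[1] * b[2]) / w, w])
                    comps = comps[:i] + [merged] + comps[i + 2:]
                    comps = _polish_components(ex, nu, comps)
                    break
            else:
                break
        comps.sort(key=lambda c: -c[1])
        full_window = (float(ex.temperature[0]), float(ex.temperature[-1]))
        transitions = [PeeledTransition(float(c[0]), float(c[1]), float(c[2]), full_window)
                       for c in comps]

    return PeelingResult(tuple(transitions), tuple(residuals), total, complete)


def check_one_stage(ex: ExcessCurve, nu: float, *, floor: float = 0.01) -> OneStageFitReport:
    """Fit the whole curve with a single one-stage transition.

    Used to validate annealed preparations (a preparation reduced to one
    surviving transition should fit at quadrature-error level) and to
    reject over-simplified models (a multi-transition curve fits badly).
    The fit is initialised from the W(T) tail line and refined by least
    squares over the full positive-signal window.
    """
    wt = compute_wt(ex, nu, floor=floor)
    sel = ex.excess_heat_capacity > 1e-6 * float(np.max(ex.excess_heat_capacity))
    dH0 = max(ex.total_enthalpy, 1e-6)
    E_a, T_star, dH = _refine_window(ex, nu, wt.E_a, wt.T_star, dH0, sel)
    p = KineticParameters(E_a, T_star)
    model = dH * arrhenius_rate(p, ex.temperature) * native_fraction_scan(p, ex.temperature, nu) / nu
    resid = (ex.excess_heat_capacity - model)[sel]
    return OneStageFitReport(E_a, T_star, dH, float(np.std(resid)),
                             float(np.max(ex.excess_heat_capacity)))
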