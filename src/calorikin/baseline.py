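"""Chemical (sigmoidal) baseline estimation for DSC thermograms.

The raw heat capacity of a denaturing protein is

    C_p(T) = C_p^N(T) (1 - xi(T)) + C_p^D(T) xi(T) + dH dxi/dT,

where xi is the degree of completeness of the transition and C_p^N /
C_p^D are the (locally linear) heat capacities of the native and
denatured states.  Only the last term — the excess heat capacity — is of
kinetic interest; the first two form the chemical baseline, which steps
sigmoidally from the native line to the denatured line across the
transition.

For a multi-transition curve the same single-xi construction is applied
under the enthalpy-proportionality assumption: each transition's
heat-capacity jump is taken proportional to its share of the total
enthalpy, which formally collapses the multi-transition baseline onto
the single-transition equation with xi = sum_i dH_i xi_i / dH.  No
per-transition jump is estimated; when the proportionality is violated
the recovered enthalpy carries a documented approximation error of a
few percent.

The algorithm is anchored on four user-selected temperatures
T1 < T2 < T3 < T4: [T1, T2] is the linear pre-transition stretch,
[T3, T4] the linear post-transition stretch.  The null baseline is the
native line, the chord of the raw curve between T2 and T3, then the
denatured line; xi and dH follow by integration, the baseline is rebuilt
from xi, and the loop repeats until dH moves by less than ``tol``
(default 0.01%) between iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_trapezoid

from .curves import CurveValidationError, ExcessCurve, Thermogram

__all__ = ["BaselineFit", "fit_baseline", "suggest_anchors"]


@dataclass(frozen=True)
class BaselineFit:
    """Result of the iterative chemical-baseline estimation.

    ``baseline`` and ``xi`` are evaluated on the analysis grid
    ``temperature`` (the [T1, T4] portion of the input grid).  ``xi`` is
    reported unclipped; values outside [0, 1] produced by noise are
    clipped only internally when the baseline is rebuilt.
    """

    anchors: tuple[float, float, float, float]
    native_line: tuple[float, float]     # (slope, intercept) of C_p^N
    denatured_line: tuple[float, float]  # (slope, intercept) of C_p^D
    temperature: np.ndarray
    baseline: np.ndarray
    xi: np.ndarray
    excess: np.ndarray
    dH: float
    n_iterations: int
    converged: bool
    heating_rate: float = 1.0

    def excess_curve(self) -> ExcessCurve:
        """C_p^ex (raw minus converged baseline) on the analysis window."""
        return ExcessCurve(self.temperature, self.excess,
                           heating_rate=self.heating_rate)


def _line_fit(T: np.ndarray, cp: np.ndarray, lo: float, hi: float, name: str):
    sel = (T >= lo - 1e-12) & (T <= hi + 1e-12)
    if sel.sum() < 3:
        raise CurveValidationError(f"{name} segment [{lo}, {hi}] contains fewer than 3 points")
    fit = stats.linregress(T[sel], cp[sel])
    return float(fit.slope), float(fit.intercept)


def fit_baseline(curve: Thermogram, anchors, *, max_iter: int = 100,
                 tol: float = 1e-4) -> BaselineFit:
    """Iterative enthalpy-proportional chemical-baseline fit.

    Parameters
    ----------
    anchors : four strictly increasing temperatures (T1, T2, T3, T4)
        inside the grid bracketing the transition region.
    tol : relative dH change that stops the iteration (default 1e-4,
        i.e. 0.01% of dH).

    Non-convergence within ``max_iter`` returns a flagged result rather
    than raising; a non-positive enthalpy at the null step raises (the
    anchors are almost certainly misplaced).
    """
    T1, T2, T3, T4 = (float(a) for a in anchors)
    if not (T1 < T2 < T3 < T4):
        raise CurveValidationError("anchors must be strictly increasing")
    T_all, cp_all = curve.temperature, curve.heat_capacity
    if T1 < T_all[0] - 1e-9 or T4 > T_all[-1] + 1e-9:
        raise CurveValidationError("anchors must lie inside the temperature grid")

    nat = _line_fit(T_all, cp_all, T1, T2, "pre-transition")
    den = _line_fit(T_all, cp_all, T3, T4, "post-transition")

    win = (T_all >= T1 - 1e-12) & (T_all <= T4 + 1e-12)
    T = T_all[win]
    cp = cp_all[win]
    cpN = nat[0] * T + nat[1]
    cpD = den[0] * T + den[1]

    # null approximation: native line, chord of the raw curve, denatured line
    base = np.where(T <= T2, cpN, np.where(T >= T3, cpD, np.nan))
    chord_sel = np.isnan(base)
    cp2 = float(np.interp(T2, T_all, cp_all))
    cp3 = float(np.interp(T3, T_all, cp_all))
    base[chord_sel] = cp2 + (cp3 - cp2) * (T[chord_sel] - T2) / (T3 - T2)

    q = cumulative_trapezoid(cp - base, T, initial=0.0)
    dH = float(q[-1])
    if dH <= 0:
        raise CurveValidationError("non-positive enthalpy at the null step; check anchor placement")
    xi = q / dH

    converged = False
    n_it = 0
    excess = cp - base
    for n_it in range(1, max_iter + 1):
        xi_c = np.clip(xi, 0.0, 1.0)
        excess = cp - cpN * (1.0 - xi_c) - cpD * xi_c
        q = cumulative_trapezoid(excess, T, initial=0.0)
        dH_new = float(q[-1])
        if dH_new <= 0:
            raise CurveValidationError("enthalpy became non-positive during iteration")
        xi = q / dH_new
        if abs(dH_new - dH) < tol * abs(dH_new):
            dH = dH_new
            converged = True
            break
        dH = dH_new

    xi_c = np.clip(xi, 0.0, 1.0)
    baseline = cpN * (1.0 - xi_c) + cpD * xi_c
    return BaselineFit((T1, T2, T3, T4), nat, den, T, baseline, xi,
                       cp - baseline, dH, n_it, converged,
                       heating_rate=curve.heating_rate)


def suggest_anchors(curve: Thermogram, *, edge_fraction: float = 0.1,
                    rise_fraction: float = 0.005) -> tuple[float, float, float, float]:
    """Heuristic anchor suggestion from the peak's rise above the edge lines.

    Fits straight lines to the first and last ``edge_fraction`` of the
    scan, then walks inward from each end until the curve departs from
    its edge line by more than ``rise_fraction`` of the peak excursion:
    T2 is the last point before the departure on the left, T3 the first
    point after the peak has rejoined the line on the right.  A starting
    point for the user, not a replacement for judgement.
    """
    T, cp = curve.temperature, curve.heat_capacity
    n = T.size
    w = max(int(edge_fraction * n), 5)
    if n < 3 * w:
        raise CurveValidationError("curve too short for anchor suggestion")

    left = stats.linregress(T[:w], cp[:w])
    right = stats.linregress(T[-w:], cp[-w:])
    dev_left = cp - (left.slope * T + left.intercept)
    dev_right = cp - (right.slope * T + right.intercept)
    peak = max(float(np.max(np.abs(dev_left))), 1e-12)
    noise = float(np.std(cp[:w] - (left.slope * T[:w] + left.intercept)))
    thr = max(rise_fraction * peak, 3.0 * noise)

    above_left = np.abs(dev_left) > thr
    i2 = int(np.argmax(above_left)) if above_left.any() else n - w
    above_right = np.abs(dev_right) > thr
    i3 = n - 1 - int(np.argmax(above_right[::-1])) if above_right.any() else w
    i2 = int(np.clip(i2, w, n - 1))
    i3 = int(np.clip(i3 + 1, 0, n - w - 1))
    if i3 <= i2:
        raise CurveValidationError("no transition region found between edge lines")
    return float(T[0]), float(T[i2 - 1]), float(T[i3]), float(T[-1])
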