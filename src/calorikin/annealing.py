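"""Annealing design: selective erasure of less stable transitions.

Because every domain signal scales linearly with its surviving fraction,
holding the sample at (T_ann, t_ann) before the scan multiplies each
transition by x_i = exp[-k_i(T_ann) t_ann].  Choosing conditions under
which the transition just below the target is practically gone
(x_{i-1} < 0.01) while the target survives appreciably (x_i > 0.1)
turns the system of annealed thermograms triangular and makes the
target transition measurable in isolation.  Holds shorter than 10 min
are unreliable (heat-up/cool-down transients), hence the floor.

Fixing the ratio A = x_{i-1}/x_i (< 0.1) gives the design curve

    t_ann = ln(A) / (k_i(T_ann) - k_{i-1}(T_ann)),

taken with the magnitude convention that yields a positive time
(k_{i-1} > k_i is required at T_ann — the less stable transition must
anneal faster), retained while t_ann <= -ln(0.1)/k_i(T_ann) and
t_ann >= 10 min.

The same inequality system bounds the method's resolving power: the
smallest parameter gap between neighbouring transitions that still
admits any feasible hold.  For equal activation energies the rate ratio
is temperature independent and the minimum T* gap is about 2 K (at
E_a ~ 300 kJ/mol near 320 K); for equal T* the minimum E_a gap depends
on the longest hold one is willing to run, so it is reported as a
function of a configurable ``max_t_ann``.

The enthalpy measured after annealing underestimates the true one by the
annealed-away fraction; ``correct_enthalpy`` inverts that loss:

    dH = dH_trans * exp[t_ann * exp((E_a/R)(1/T* - 1/T_ann))].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinetics import (
    GAS_CONSTANT,
    DomainModel,
    KineticParameters,
    arrhenius_rate,
    isothermal_fractions,
)

__all__ = [
    "AnnealingPlan",
    "plan_annealing",
    "resolving_power",
    "correct_enthalpy",
]

#: Hard constraints of the feasibility system.
X_PREV_MAX = 0.01
X_TARGET_MIN = 0.1
MIN_T_ANN = 10.0  # minutes


@dataclass(frozen=True)
class AnnealingPlan:
    """One candidate hold with its predicted per-transition survival."""

    T_ann: float                 # K
    t_ann: float                 # min
    ratio: float                 # A = x_{i-1}/x_i as designed
    survival: tuple[float, ...]  # per transition, in model order
    domain_fractions: tuple      # isothermal_fractions output, per domain
    feasible: bool


def plan_annealing(model: DomainModel, target_index: int, A: float,
                   T_ann_grid) -> list[AnnealingPlan]:
    """Design (T_ann, t_ann) pairs that erase transitions below the target.

    ``target_index`` is the 1-based transition number (in order of
    increasing thermostability, counting both stages of a two-stage
    domain); there must be a transition below it to anneal away.
    ``A`` is the designed survival ratio x_{i-1}/x_i (< 0.1).

    Returns one plan per grid temperature; infeasible points carry
    ``feasible=False`` with their (out-of-range) t_ann as a diagnostic,
    so an empty feasible set still shows the closest-to-feasible hold.
    """
    params = model.transition_parameters()
    if not 2 <= target_index <= len(params):
        raise ValueError("target_index must name a transition with a less stable neighbour")
    if not 0 < A < X_TARGET_MIN:
        raise ValueError("ratio A must lie in (0, 0.1)")
    p_prev = params[target_index - 2]
    p_target = params[target_index - 1]

    plans: list[AnnealingPlan] = []
    for T_ann in np.atleast_1d(np.asarray(T_ann_grid, dtype=float)):
        k_prev = arrhenius_rate(p_prev, T_ann)
        k_tgt = arrhenius_rate(p_target, T_ann)
        if k_prev <= k_tgt:
            continue  # the neighbour would not anneal faster: unusable temperature
        t_ann = abs(math.log(A)) / (k_prev - k_tgt)
        fractions = isothermal_fractions(model, float(T_ann), t_ann)
        survival = _per_transition_survival(model, fractions)
        x_prev = survival[target_index - 2]
        x_tgt = survival[target_index - 1]
        feasible = (t_ann >= MIN_T_ANN) and (x_tgt > X_TARGET_MIN) and (x_prev < X_PREV_MAX)
        plans.append(AnnealingPlan(float(T_ann), float(t_ann), A,
                                   survival, tuple(fractions), feasible))
    return plans


def _per_transition_survival(model: DomainModel, fractions) -> tuple[float, ...]:
    """Surviving fraction per transition: the one-stage x, or (x_N,
    x_N + x_I) for the two stages of a two-stage domain (stage 2 still
    fires for molecules in either N or I)."""
    out: list[float] = []
    for d, fr in zip(model.domains, fractions):
        if len(fr) == 1:
            out.append(fr[0])
        else:
            xN, xI = fr
            out.extend([xN, xN + xI])
    return tuple(out)


def _gap_feasible_equal_Ea(E_a: float, T_low: float, gap: float,
                           T_ann_grid: np.ndarray, max_t_ann: float) -> bool:
    p_prev = KineticParameters(E_a, T_low)
    p_tgt = KineticParameters(E_a, T_low + gap)
    return _any_feasible(p_prev, p_tgt, T_ann_grid, max_t_ann)


def _any_feasible(p_prev: KineticParameters, p_tgt: KineticParameters,
                  T_ann_grid: np.ndarray, max_t_ann: float) -> bool:
    k_prev = arrhenius_rate(p_prev, T_ann_grid)
    k_tgt = arrhenius_rate(p_tgt, T_ann_grid)
    # hold must kill the neighbour (x < 0.01), spare the target (x > 0.1):
    # exists t in [max(10, 2 ln10 / k_prev), min(max_t, ln10 / k_tgt)]
    t_lo = np.maximum(MIN_T_ANN, 2.0 * math.log(10.0) / k_prev)
    t_hi = np.minimum(max_t_ann, math.log(10.0) / k_tgt)
    return bool(np.any(t_lo < t_hi))


def resolving_power(E_a_base: float, T_star_base: float, *,
                    max_t_ann: float = 60.0,
                    gap_resolution_K: float = 0.01,
                    gap_resolution_Ea: float = 1.0,
                    T_ann_span: float = 40.0) -> tuple[float, float]:
    """Smallest resolvable parameter gaps between two one-stage domains.

    Returns ``(min_dEa, min_dT_star)``:

    * ``min_dT_star`` — equal activation energies (both ``E_a_base``),
      less stable domain at ``T_star_base``; smallest T* gap admitting a
      feasible hold.  The rate ratio is temperature independent here, so
      this limit does not depend on ``max_t_ann``.
    * ``min_dEa`` — equal T* (both ``T_star_base``); smallest E_a gap
      (less stable domain has the smaller E_a) admitting a feasible hold
      no longer than ``max_t_ann`` minutes.  Without a time ceiling this
      limit shrinks toward zero, so the ceiling is part of the contract.

    Both are found by scanning the gap downward on a grid of candidate
    holds (T_ann over ``T_star_base`` +/- ``T_ann_span``, feasibility of
    the hold interval checked in closed form).
    """
    if not (E_a_base > 0 and T_star_base > 0):
        raise ValueError("base parameters must be positive")
    T_grid = np.arange(max(T_star_base - T_ann_span, 1.0),
                       T_star_base + T_ann_span, 0.1)

    # equal-E_a limit: scan the T* gap downward until infeasible
    gap = 5.0
    min_gap_T = math.nan
    while gap > gap_resolution_K / 2:
        if _gap_feasible_equal_Ea(E_a_base, T_star_base, gap, T_grid, max_t_ann):
            min_gap_T = gap
            gap -= gap_resolution_K
        else:
            break

    # equal-T* limit: less stable domain gets the smaller E_a
    dEa = min(300.0, E_a_base - 1.0)
    min_gap_E = math.nan
    while dEa > gap_resolution_Ea / 2:
        p_prev = KineticParameters(E_a_base - dEa, T_star_base)
        p_tgt = KineticParameters(E_a_base, T_star_base)
        if _any_feasible(p_prev, p_tgt, T_grid, max_t_ann):
            min_gap_E = dEa
            dEa -= gap_resolution_Ea
        else:
            break

    return min_gap_E, min_gap_T


def correct_enthalpy(dH_trans: float, p: KineticParameters,
                     T_ann: float, t_ann: float) -> float:
    """Undo the annealing loss in a measured transition enthalpy.

    ``dH_trans`` is the area measured after a (T_ann, t_ann) hold; the
    returned dH divides out the surviving fraction
    exp[-k(T_ann) t_ann].  The correction factor is always >= 1.
    """
    if t_ann < 0:
        raise ValueError("annealing time must be non-negative")
    return dH_trans * math.exp(t_ann * math.exp(
        (p.E_a / GAS_CONSTANT) * (1.0 / p.T_star - 1.0 / T_ann)))
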