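"""Synthetic datasets with known ground truth for every analysis stage.

No instrument data is deposited for the study system (the two isoforms
of the isolated myosin head), so every pipeline is exercised on
synthetic inputs generated from the published fitted parameters: a
two-domain model whose less stable domain (the regulatory domain)
denatures in one stage and whose more stable domain (the motor domain)
denatures in two stages, scanned at 1 K/min.  Defaults reproduce the
S1(A1) / 100 mM KCl parameter set:

    domain I:           E_a = 290 kJ/mol, T* = 317.5 K, dH = 200 kJ/mol
    domain II stage 1:  E_a = 400 kJ/mol, T* = 321.2 K, dH1 = 1030 kJ/mol
    domain II stage 2:  E_a = 340 kJ/mol, T* = 324.5 K, dH2 = 500 kJ/mol

with annealing holds 319.15 K/15 min and 315.15 K/20 min (plus a
317.15 K/17 min holdout), a chemical baseline built with the
enthalpy-proportional jump, additive Gaussian noise scaled to peak
height, DLS radius growth with the published Arrhenius law
(E_a = 430 kJ/mol, T* = 320.8 K), fluorescence parameter-A plateaus
1.06 -> 1.32 tracking the two-stage domain, and inactivation following
the domain II stage 1 law.

Every generator is seeded and bit-reproducible, and returns the ground
truth alongside the dataset; recovery tests assert against that record.
Noise magnitudes are this package's own choices (no magnitudes are
published): 1% of peak height for DSC, 3% multiplicative for DLS, 5%
additive for activity.  Not emulated: instrument response convolution,
DLS intensity weighting, temperature-scale mismatch between probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .curves import ProbeTrace, Thermogram
from .kinetics import (
    DomainModel,
    KineticParameters,
    OneStageDomain,
    TwoStageDomain,
    anneal_model,
    arrhenius_rate,
    default_grid,
    simulate_model,
    two_stage_state_fractions,
)

__all__ = [
    "GeneratorConfig",
    "s1a1_model",
    "make_thermogram_set",
    "make_dls_set",
    "make_probe_set",
]

LN2 = float(np.log(2.0))


def s1a1_model() -> DomainModel:
    """Default two-domain model (S1(A1)-like, high ionic strength)."""
    return DomainModel((
        OneStageDomain(KineticParameters(290.0, 317.5), 200.0),
        TwoStageDomain(KineticParameters(400.0, 321.2),
                       KineticParameters(340.0, 324.5),
                       1030.0, 500.0),
    ))


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generators, with study-default values."""

    model: DomainModel = field(default_factory=s1a1_model)
    nu: float = 1.0                      # scan rate [K/min]
    T0: float = 288.15                   # scan start [K]
    span: float = 70.0                   # scan length [K]
    step: float = 0.05                   # grid spacing [K]
    # chemical baseline: native line cp = slope*T + intercept; the
    # denatured line is offset by a heat-capacity jump equal to
    # ``dCp_fraction`` of the peak height, apportioned by enthalpy share
    baseline_slope: float = 0.02         # kJ/(mol K)/K
    baseline_intercept: float = 20.0     # kJ/(mol K) at 0 K (line formula)
    dCp_fraction: float = 0.1
    noise_fraction: float = 0.01         # DSC additive noise, x peak height
    annealing_schedule: tuple = ((319.15, 15.0), (315.15, 20.0))
    holdout_annealing: tuple = (317.15, 17.0)
    # DLS growth law and trace layout
    dls_Ea: float = 430.0                # kJ/mol
    dls_T_star: float = 320.8            # K
    dls_R_h0: float = 20.0               # nm
    dls_temperatures: tuple = (312.15, 314.15, 316.15, 318.15, 320.15)  # 39-47 degC
    dls_lag_range: tuple = (2.0, 8.0)    # t_0 drawn uniformly [min]
    dls_noise: float = 0.03              # multiplicative
    # fluorescence plateaus of parameter A; A_mid is the level between
    # the two stages of the two-stage domain
    A_low: float = 1.06
    A_mid: float = 1.19
    A_high: float = 1.32
    fluor_noise: float = 0.0
    # inactivation traces
    inactivation_temperatures: tuple = (312.15, 314.15, 316.15, 318.15, 320.15)
    inactivation_noise: float = 0.05

    def grid(self) -> np.ndarray:
        return default_grid(self.T0, self.span, self.step)


def _two_stage_domain(model: DomainModel) -> TwoStageDomain:
    for d in model.domains:
        if isinstance(d, TwoStageDomain):
            return d
    raise ValueError("config model has no two-stage domain")


def make_thermogram_set(cfg: GeneratorConfig = GeneratorConfig(), *, seed: int = 0,
                        include_holdout: bool = True) -> dict:
    """Native + annealed raw thermograms with chemical baseline and noise.

    Returns ``{"native": Thermogram, "annealed": [...], "holdout": ...,
    "excess": {...}, "truth": {...}}``; the ``excess`` entry holds the
    noise- and baseline-free excess curves the thermograms were built
    from.  Zero noise and a zero baseline reproduce the kinetic
    simulation exactly.
    """
    rng = np.random.default_rng(seed)
    grid = cfg.grid()
    histories: list[tuple[float, float] | None] = [None, *cfg.annealing_schedule]
    if include_holdout:
        histories.append(cfg.holdout_annealing)

    curves = {}
    excess = {}
    peak_native = None
    for hist in histories:
        model = cfg.model if hist is None else anneal_model(cfg.model, *hist)
        ex = simulate_model(model, grid, cfg.nu)
        if peak_native is None:
            peak_native = float(np.max(ex.excess_heat_capacity))
        base = _chemical_baseline(cfg, ex, peak_native)
        cp = base + ex.excess_heat_capacity
        if cfg.noise_fraction > 0:
            cp = cp + cfg.noise_fraction * peak_native * rng.standard_normal(grid.size)
        name = "native" if hist is None else f"annealed_{hist[0]:.2f}K_{hist[1]:.0f}min"
        curves[name] = Thermogram(grid, cp, heating_rate=cfg.nu,
                                  annealing_history=hist, label=name)
        excess[name] = ex

    names = list(curves)
    out = {
        "native": curves[names[0]],
        "annealed": [curves[n] for n in names[1:1 + len(cfg.annealing_schedule)]],
        "excess": excess,
        "truth": {
            "model": cfg.model,
            "nu": cfg.nu,
            "annealing_schedule": cfg.annealing_schedule,
            "holdout_annealing": cfg.holdout_annealing if include_holdout else None,
            "baseline": (cfg.baseline_slope, cfg.baseline_intercept, cfg.dCp_fraction),
            "noise_fraction": cfg.noise_fraction,
            "seed": seed,
        },
    }
    if include_holdout:
        out["holdout"] = curves[names[-1]]
    return out


def _chemical_baseline(cfg: GeneratorConfig, ex, peak_native: float) -> np.ndarray:
    """Native line stepping to the denatured line along the
    enthalpy-weighted completeness of the simulated transitions."""
    T = ex.temperature
    cpN = cfg.baseline_slope * T + cfg.baseline_intercept
    dCp = cfg.dCp_fraction * peak_native
    q = ex.cumulative_heat
    total = q[-1]
    xi = q / total if total > 0 else np.zeros_like(q)
    return cpN + dCp * xi


def make_dls_set(cfg: GeneratorConfig = GeneratorConfig(), *, seed: int = 0,
                 n_concentrations: int = 3, t_max: float = 40.0,
                 dt: float = 0.25, noise: float | None = None) -> dict:
    """Isothermal radius-growth traces plus a temperature-scan trace.

    * a temperature series at the configured hold temperatures (one
      trace each, t_0 drawn per trace);
    * a concentration series at 317.15 K (44 degC): identical growth law,
      different lags — the doubling time is concentration independent by
      construction;
    * a scan trace R_h(T) at the configured rate whose onset sits a few
      kelvin above the two-stage domain's stage-1 midpoint (nucleation
      delay), built with a 3 K offset.
    """
    rng = np.random.default_rng(seed)
    if noise is None:
        noise = cfg.dls_noise
    law = KineticParameters(cfg.dls_Ea, cfg.dls_T_star)

    def one_trace(T_hold: float) -> tuple[ProbeTrace, dict]:
        t2R = LN2 / arrhenius_rate(law, T_hold)
        t0 = float(rng.uniform(*cfg.dls_lag_range))
        t = np.arange(0.0, t_max + dt / 2, dt)
        r = np.where(t <= t0, cfg.dls_R_h0,
                     cfg.dls_R_h0 * np.exp(LN2 / t2R * (t - t0)))
        if noise > 0:
            r = r * np.exp(noise * rng.standard_normal(t.size))
        trace = ProbeTrace(t, r, hold_temperature=T_hold, kind="dls")
        return trace, {"t_2R": t2R, "t_0": t0, "R_h0": cfg.dls_R_h0}

    temp_series, temp_truth = [], []
    for T_hold in cfg.dls_temperatures:
        tr, tru = one_trace(T_hold)
        temp_series.append(tr)
        temp_truth.append(tru)

    conc_series, conc_truth = [], []
    for _ in range(n_concentrations):
        tr, tru = one_trace(317.15)
        conc_series.append(tr)
        conc_truth.append(tru)

    # constant-rate scan trace: the radius crosses the 100 nm onset
    # threshold 3 K above the stage-1 midpoint (nucleation delay)
    d2 = _two_stage_domain(cfg.model)
    grid = cfg.grid()
    xN, _, _ = two_stage_state_fractions(d2, grid, cfg.nu)
    conv = 1.0 - xN / max(d2.x_N0, 1e-300)
    j = int(np.argmax(conv >= 0.5))
    T_mid = float(grid[j])
    onset_offset = 3.0
    onset_threshold = 100.0
    growth_per_K = 1.5
    T_on = T_mid + onset_offset  # where R_h = onset_threshold
    T_start = T_on - math.log(onset_threshold / cfg.dls_R_h0) / growth_per_K
    growth = np.where(grid <= T_start, cfg.dls_R_h0,
                      cfg.dls_R_h0 * np.exp(growth_per_K * (grid - T_start)))
    scan_trace = ProbeTrace(grid, np.minimum(growth, 3000.0), kind="dls_scan")

    return {
        "temperature_series": temp_series,
        "concentration_series": conc_series,
        "scan_trace": scan_trace,
        "truth": {
            "arrhenius": law,
            "temperature_series": temp_truth,
            "concentration_series": conc_truth,
            "scan_onset_K": T_on,
            "scan_stage1_midpoint_K": T_mid,
            "noise": noise,
            "seed": seed,
        },
    }


def make_probe_set(cfg: GeneratorConfig = GeneratorConfig(), *, seed: int = 0,
                   t_max: float = 30.0, n_time_points: int = 13,
                   quench_drop: float = 0.5) -> dict:
    """Fluorescence scan plus inactivation time courses, with truth.

    The spectral parameter A steps from ``A_low`` to ``A_mid`` along
    stage-1 conversion of the two-stage domain and on to ``A_high``
    along stage-2 conversion; both channels share a common linear
    thermal quenching (I365 drops by ``quench_drop`` over the scan), so
    A is gain- and quench-invariant by construction.  Inactivation
    activities decay with the stage-1 rate constant at each hold
    temperature.
    """
    rng = np.random.default_rng(seed)
    d2 = _two_stage_domain(cfg.model)
    grid = cfg.grid()[:: max(1, int(round(1.0 / cfg.step)))]  # ~1 K sampling
    xN, _, xD = two_stage_state_fractions(d2, grid, cfg.nu)
    conv1 = 1.0 - xN / max(d2.x_N0, 1e-300)
    conv2 = xD / max(d2.x_N0 + d2.x_I0, 1e-300)
    A = cfg.A_low + (cfg.A_mid - cfg.A_low) * conv1 + (cfg.A_high - cfg.A_mid) * conv2
    quench = 1.0 - quench_drop * (grid - grid[0]) / (grid[-1] - grid[0])
    I365 = 100.0 * quench
    I320 = A * I365
    if cfg.fluor_noise > 0:
        I320 = I320 * (1.0 + cfg.fluor_noise * rng.standard_normal(grid.size))
        I365 = I365 * (1.0 + cfg.fluor_noise * rng.standard_normal(grid.size))
    fluor = ProbeTrace(grid, I320, ordinate2=I365, kind="fluorescence")

    stage1 = d2.stage1
    inact_traces = []
    inact_truth = []
    for T_hold in cfg.inactivation_temperatures:
        k = arrhenius_rate(stage1, T_hold)
        # sample each hold over ~4 decay constants (experiment design:
        # fast-inactivating holds are sampled more densely in time)
        t = np.linspace(0.0, min(t_max, 4.0 / k), n_time_points)
        y = np.exp(-k * t)
        if cfg.inactivation_noise > 0:
            y = y + cfg.inactivation_noise * rng.standard_normal(t.size)
        inact_traces.append(ProbeTrace(t, y, hold_temperature=T_hold, kind="activity"))
        inact_truth.append({"temperature_K": T_hold, "k": k})

    return {
        "fluorescence": fluor,
        "inactivation": inact_traces,
        "truth": {
            "A_levels": (cfg.A_low, cfg.A_mid, cfg.A_high),
            "A_curve": A,
            "stage1": stage1,
            "inactivation": inact_truth,
            "seed": seed,
        },
    }
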