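# Methods

This note records the model, the numerical choices and the judgement
calls behind `calorikin`, at the level a maintainer or a careful user
needs. Everything quantitative stated here is computed by the test
suite or `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Kinetic model and units

Each calorimetric domain denatures irreversibly, one-stage (N → D) or
two-stage (N → I → D), each step first order with the Arrhenius law in
the (E_a, T*) form, k(T) = exp[(E_a/R)(1/T* − 1/T)]. Units are fixed
throughout: E_a in kJ/mol with R = 8.314×10⁻³ kJ/(mol·K), rate constants
in min⁻¹ (so T* is the temperature of k = 1 min⁻¹), heating rates in
K/min, temperatures in kelvin internally (files may declare °C and are
converted on read). Enthalpies are per mole of protein, kJ/mol; the
excess heat capacity is kJ/(mol·K).

Assumptions: ΔH of each stage is temperature independent and positive;
domains are kinetically independent; annealing scales each domain's
signal by its surviving fraction without changing the peak shape.
Reversible (equilibrium) thermodynamics, pressure dependence, and
non-Arrhenius rate laws are out of scope.

## Numerical solution of the scan equations

All temperature integrals are cumulative trapezoids on the supplied
grid; grids may be non-uniform (instrument exports are). The default
synthetic grid is 0.05 K over [288.15, 358.15] K. The one-stage
survival x(T) is the exponential of the trapezoid integral of k.

The two-stage system dx_N/dT = −k₁x_N/ν, dx_I/dT = (k₁x_N − k₂x_I)/ν is
stiff where the rates are large, so it is advanced with a
piecewise-exact exponential step: rates are frozen per grid interval at
their endpoint average, for which the sequential linear system has a
closed form (including the removable k₁ = k₂ singularity, switched to
the limit formula when |k₁−k₂| < 10⁻¹⁰k₁). Freezing at the *average*
rather than midpoint rate makes the pure-decay limits reproduce the
one-stage trapezoid exponent exactly, so an annealed preparation with
x_N0 = 0 coincides with the one-stage simulation to machine-level
consistency. The scheme is unconditionally stable and second order; the
tests verify ≤10⁻⁴ relative agreement (of the peak) against an
independent implicit (Radau) integration, and enthalpy conservation to
≤0.5% quadrature error. Isothermal holds use the exact closed-form
solution, not the stepper.

## W(T) and recursive peeling

W(T) = T(ln ν + ln C_p^ex − ln ∫_T^end C_p^ex dT) equals T·ln k for a
one-transition curve, hence is linear with slope E_a/(RT*) and intercept
−E_a/R. Points where C_p^ex ≤ 0 or where the remaining tail area falls
below 1% of the total are masked (the log of the tail integral blows up
there), never extrapolated.

The linear tail window is found by extending downward from the hottest
unmasked point while the straight-line residual SD stays below a
threshold: twice a local noise estimate (robust MAD of second
differences), with a small absolute floor for noiseless data. These
thresholds, and the ≥15-point minimum window, are this package's own —
there is no canonical rule for "the tail is linear".

Greedy peeling (estimate the tail transition, fit its ΔH by least
squares of C_p^ex against k·x/ν in the window, re-optimise locally,
subtract, repeat until <3% of the area remains) accumulates subtraction
error: on the reference two-domain model it splits the least stable
domain and reports four transitions. The implementation therefore
finishes with (i) a joint least-squares polish of all peeled one-stage
components on the full curve, (ii) pruning of components below the stop
fraction, and (iii) merging of components whose T* values are closer
than the ~2 K resolving limit of the annealing method — transitions
closer than that are physically inseparable and count as one apparent
transition. With this refinement the reference model yields three
apparent transitions, clean single- and double-transition curves are
recovered essentially exactly (T* within 0.3 K at zero noise across
random two-transition models), and all peeled parameters remain labelled
what they are: null approximations.

## Chemical baseline

The raw signal is C_p^N(1−ξ) + C_p^Dξ + C_p^ex with linear C_p^N and
C_p^D fitted on user-anchored segments [T1,T2] and [T3,T4]. The null
baseline uses the chord of the raw curve between T2 and T3 (used as
written even across local dips); each iteration recomputes ξ from the
cumulative excess heat and rebuilds the baseline until ΔH moves by less
than 0.01% (default; `tol` configurable; max 100 iterations,
non-convergence flagged rather than raised). ξ is clipped to [0,1] for
baseline construction but reported unclipped.

Multi-transition curves use the same single-ξ construction under the
enthalpy-proportional jump assumption (each transition's ΔC_p share
equals its ΔH share); on synthetic data violating proportionality
maximally, the recovered total ΔH is still within ~5%.

Accuracy is anchor-sensitive: because these broad kinetic transitions
have long low-temperature tails, the pre-transition segment must end
before ~0.5% conversion or the fitted native line tilts and the error
extrapolates across the window. The automatic anchor suggestion (edge
lines plus a departure threshold of 0.5% of the peak excursion or 3× the
edge noise) is a starting point, not a substitute for inspection; with
well-placed anchors single-peak recovery is better than 1%.

## Annealing design and resolving power

Fixing the survival ratio A = x_{i−1}/x_i gives the design curve
t_ann = |ln A|/(k_{i−1} − k_i), taken with the magnitude convention that
requires k_{i−1} > k_i at the hold temperature (the sign of the raw
expression depends on ordering). A plan is feasible when the *coupled*
survivals satisfy x_{i−1} < 0.01 and x_i > 0.1 and the hold is ≥10 min
(shorter holds are dominated by heat-up/cool-down transients). For
two-stage domains the hold updates both x_N0 and x_I0 for the
downstream scan; stage-2 "survival" counts molecules in N or I, since
both still release the stage-2 enthalpy.

The resolving-power search scans the parameter gap downward until no
feasible hold exists. At equal E_a the rate ratio is temperature
independent and the minimum T* gap is ≈2 K at E_a = 300 kJ/mol near
320 K (scaling as RT²ln2/E_a, so doubling E_a halves it). At equal T*
the limit is finite only given a maximum acceptable hold; it is exposed
as `max_t_ann` (default 60 min, giving ≈64 kJ/mol; ~20 min holds give
≈140–150 kJ/mol) and reported as a function of that choice rather than
asserted as a constant.

Enthalpies measured after annealing are corrected by dividing out the
surviving fraction, ΔH = ΔH_trans·exp[t_ann·k(T_ann)]; the round trip
simulate → anneal → measure → correct closes to <1%.

## Joint fit, uncertainties, counter-test

The joint fit is scipy's trust-region-reflective least squares over all
observations at once, uniform per-point weighting, bounds E_a ∈ [50,
1000] kJ/mol, T* ∈ [280, 360] K, ΔH ∈ (0, 5000] kJ/mol, with
multi-start (default 8 starts, ±20% seeded jitter around the peeled
initial values — the null approximation is deliberately distrusted). A
common normalisation across curves is assumed (no per-curve scale
factor). On noiseless synthetic native + two annealed scans the
generating parameters are recovered within (0.1 K, 10 kJ/mol, 2%), and
holdout annealings are predicted within 1% of peak height.

Uncertainties are *not* regression covariances: the dominant errors of
this kind of experiment are systematic (baseline placement, temperature
calibration). Each observation is refit alone and the largest deviation
of any single-curve estimate from the joint estimate is reported,
floored at 0.4 K (T*), 40 kJ/mol (E_a) and 10% (ΔH).

The constrained counter-fit freezes a parameter at a hypothesised value,
refits the rest, and compares holdout predictions. Discrimination
requires a holdout in which the disputed parameter still matters: for a
domain-I T* dispute the validating hold must leave domain I partially
alive (a mild ~40 °C hold), otherwise the free parameters compensate
and the test is blunt. The test suite uses such a discriminating design.

## Probes

DLS growth fits estimate (t_0, R_h0, t_2R) by an exact change-point
search on log R_h (flat, then linear, continuous at the break) polished
by nonlinear least squares; t_0 is a nuisance parameter (nucleation,
irreproducible between runs). The growth rate entering the Arrhenius
fit is k_agg = ln 2/t_2R — chosen for consistency with the half-life
t_0.5 = ln 2/k, so that t_2R(T*) = ln 2 min; a 1/t_2R convention would
shift T* but not E_a.

Phase-plot segmentation uses |dA/dT| change points (threshold 10% of the
maximum slope, with an absolute floor so a flat scan is one state), a
valley split for two merging transition peaks, and a per-segment
through-origin test (95% CI of the extrapolated intercept, padded by 2%
of the intensity scale). Segments are reported as temperature ranges
and classifications only — no kinetic parameters are extracted from
phase plots, which are too error-sensitive for that. Fluorescence
assignment additionally reports the RMS mismatch between A_norm and each
transition's conversion curve (and the enthalpy-weighted two-stage
combination), which is more robust than window containment alone when
transitions overlap.

Inactivation traces are fit as activity = exp(−kt) with amplitude fixed
at 1 (pre-normalised activities; a free-amplitude flag exists), k ≥ 0,
the boundary flagged when the decay over the observed span is <0.1%.

## Synthetic data: what it does and does not emulate

The generators default to the reference conditions: the two-domain
model (domain I: 290 kJ/mol, 317.5 K, 200 kJ/mol; domain II stage 1:
400 kJ/mol, 321.2 K, 1030 kJ/mol; stage 2: 340 kJ/mol, 324.5 K,
500 kJ/mol), 1 K/min scans, annealing holds 319.15 K/15 min and
315.15 K/20 min plus a 317.15 K/17 min holdout, DLS growth law
E_a = 430 kJ/mol, T* = 320.8 K at 39–47 °C holds, parameter-A plateaus
1.06 → 1.32, inactivation following the stage-1 law. Noise magnitudes
are this package's choices (none are published): additive Gaussian at 1%
of peak height for DSC, 3% multiplicative for DLS radii, 5% additive for
activities; the chemical baseline jump defaults to 10% of peak height,
apportioned by enthalpy share. Inactivation holds are sampled over ~4
decay constants per temperature (fast holds sampled densely), as a real
experiment would be designed.

Not emulated: instrument time-response convolution (a pluggable
pre-processing hook accepts a user-supplied correction), DLS
intensity-weighting and polydispersity artifacts, temperature-scale
mismatch between instruments, and cell-volume/concentration conversion
from raw power. Passing recovery tests on these generators therefore
demonstrates correctness of the estimators under the stated model, not
robustness to every instrumental artifact of real data.

## Known limitations

- Peeling thresholds (tail floor 1%, stop fraction 3%, window ≥15
  points, 2 K merge gap) are defaults verified on the synthetic
  conditions above; strongly overlapping transitions with comparable
  enthalpies may still merge or split differently.
- The chemical baseline is deliberately linear-by-segment; curved
  pre/post-transition heat capacities would need polynomial segments.
- The counter-fit's power depends on the holdout design (see above); it
  reports ratios, and leaves the accept/reject judgement to the user.
- The equal-T* resolving-power limit is a function of `max_t_ann` by
  construction, not a universal constant.
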