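"""Full DSC analysis pipeline: baseline, peeling, annealing, joint fit.

Generates a synthetic experiment exactly as it would be run: a native
1 K/min scan plus two scans after annealing holds (319.15 K/15 min and
315.15 K/20 min), each with a sigmoidal chemical baseline and no noise.
The chemical baseline is removed iteratively, the native curve is peeled
for starting values, and all three curves are fit jointly with the
two-domain model (one-stage + two-stage).  The fitted parameters should
match the generating ones to numerical precision; the printed
uncertainties are the reproducibility floors (0.4 K, 40 kJ/mol, 10%).
"""

from calorikin import (
    DomainModel,
    FitProblem,
    KineticParameters,
    OneStageDomain,
    TwoStageDomain,
    estimate_uncertainty,
    fit_baseline,
    fit_model,
    peel_transitions,
)
from calorikin.baseline import suggest_anchors
from calorikin.synth import GeneratorConfig, make_thermogram_set

cfg = GeneratorConfig(noise_fraction=0.0)
data = make_thermogram_set(cfg, seed=1, include_holdout=False)

observations = []
native_excess = None
for tg in [data["native"], *data["annealed"]]:
    fit = fit_baseline(tg, suggest_anchors(tg))
    print(f"{tg.label or 'native':34s} baseline dH = {fit.dH:7.1f} kJ/mol "
          f"({fit.n_iterations} iterations)")
    ex = fit.excess_curve()
    observations.append((ex, tg.annealing_history))
    if tg.annealing_history is None:
        native_excess = ex

peel = peel_transitions(native_excess, cfg.nu)
t3, t2, t1 = peel.transitions
template = DomainModel((
    OneStageDomain(KineticParameters(t1.E_a, t1.T_star), t1.dH),
    TwoStageDomain(KineticParameters(t2.E_a, t2.T_star),
                   KineticParameters(t3.E_a, t3.T_star), t2.dH, t3.dH),
))

problem = FitProblem(tuple(observations), template)
result = fit_model(problem, n_starts=4)
unc = estimate_uncertainty(problem, result, n_starts=1)

print(f"\njoint fit converged: {result.converged}")
print(f"{'parameter':14s} {'fitted':>9s} {'+/-':>7s}   generating value")
truth = {
    "d0.E_a": 290.0, "d0.T_star": 317.5, "d0.dH": 200.0,
    "d1.s1.E_a": 400.0, "d1.s1.T_star": 321.2, "d1.s1.dH": 1030.0,
    "d1.s2.E_a": 340.0, "d1.s2.T_star": 324.5, "d1.s2.dH": 500.0,
}
for name, value in result.parameters.items():
    print(f"{name:14s} {value:9.2f} {unc[name]:7.2f}   {truth[name]:.1f}")
print("\nThe two annealed scans break the degeneracy between 'three")
print("independent domains' and 'two domains, one denaturing in two stages'.")
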