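"""Identify the denaturation step that limits thermal aggregation.

Generates isothermal DLS radius-growth traces at 39-47 degC from an
Arrhenius growth law (E_a = 430 kJ/mol, T* = 320.8 K), fits each trace
with the lagged exponential R_h = R_h0 exp[ln2/t_2R (t - t_0)], converts
doubling times to rates (k_agg = ln2 / t_2R), refits the Arrhenius law,
and compares the doubling times with the half-lives of every transition
of the calorimetric model.  The transition whose half-life matches t_2R
across temperatures is the rate-limiting denaturation step.
"""

from calorikin import (
    compare_with_denaturation,
    fit_aggregation_arrhenius,
    fit_growth,
)
from calorikin.synth import GeneratorConfig, make_dls_set, s1a1_model

data = make_dls_set(GeneratorConfig(), seed=1, noise=0.0)

fits = [fit_growth(trace) for trace in data["temperature_series"]]
print(f"{'T [degC]':>9s} {'t_2R [min]':>11s} {'lag t_0 [min]':>14s}")
for f in fits:
    print(f"{f.hold_temperature - 273.15:9.1f} {f.t_2R:11.2f} {f.t_0:14.2f}")

arr = fit_aggregation_arrhenius(fits)
print(f"\ngrowth-process Arrhenius fit: E_a = {arr.E_a:.0f} kJ/mol, "
      f"T* = {arr.T_star:.1f} K")

table = compare_with_denaturation(arr, s1a1_model())
mean_dev = table.groupby("transition")["relative_deviation"].mean()
print("\nmean |t_0.5 - t_2R| / t_2R per candidate transition:")
for name, dev in mean_dev.items():
    print(f"  {name:20s} {dev:8.3f}")
print(f"\nbest match: {mean_dev.idxmin()} — its first-order denaturation")
print("step limits the aggregate growth (the lag t_0 is nucleation and")
print("varies between runs without affecting t_2R).")
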