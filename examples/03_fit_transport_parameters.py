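"""Extract transport parameters from a synthetic measurement series.

Runs the estimation chain on the short-segment fixture: reorganization
energy lambda (log G vs 1/T with the T^(-3/2) term), Arrhenius activation
energy U_A, the 20%-deviation crossover temperature, and the low-temperature
power-law exponents alpha (vs T) and beta (vs E).
"""

import numpy as np

from fiberhop import (
    fit_arrhenius,
    fit_marcus_lambda,
    fit_power_law_field,
    fit_power_law_temperature,
    detect_crossover,
    fixture_fig3d,
    generate_ivt,
    zero_bias_conductance,
)

dataset = generate_ivt(fixture_fig3d(seed=0, noise=0.02))
T, G0 = [], []
for trace in dataset.traces:
    if not trace.fully_masked:
        T.append(trace.temperature)
        G0.append(zero_bias_conductance(trace))
T, G0 = np.array(T), np.array(G0)

lam = fit_marcus_lambda(T, G0, T_min=100.0)
arr = fit_arrhenius(T, G0, T_min=100.0)
cx = detect_crossover(T, G0, arr)
alpha = fit_power_law_temperature(T, G0, T_range=(20.0, 100.0))

coldest = dataset.traces[-1]
ok = ~coldest.mask & (coldest.bias > 0)
E = coldest.bias[ok] / coldest.segment_length
Gv = coldest.current[ok] / coldest.bias[ok]
sel = E >= np.median(E)
beta = fit_power_law_field(E[sel], Gv[sel])

print(f"lambda   = {lam.lambda_meV:6.1f} meV   (generator: 160 meV)")
print(f"U_A      = {arr.U_A_meV:6.1f} meV   (= lambda/4 - 3/2 kB Tbar)")
print(f"T_C      = {cx.T_C} K  (20% deviation from the Arrhenius fit)")
print(f"alpha    = {alpha.exponent:6.2f}      (G ~ T^alpha, 20-100 K)")
print(f"beta     = {beta.exponent:6.2f}      (G ~ E^beta at "
      f"{coldest.temperature:.0f} K)")
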