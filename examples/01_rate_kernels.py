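"""Single-hop rate kernels: thermally activated vs nuclear-tunneling transfer.

Evaluates the classical Marcus rate and the single-quantum-mode (Jortner)
rate at zero driving force on a cooldown, and prints the crossover
temperature T_C = hbar<w>/k_B separating the two regimes.
"""

import numpy as np

from fiberhop import (
    JortnerParams,
    MarcusParams,
    crossover_temperature,
    jortner_rate,
    marcus_forward_rate,
    wavenumber_to_energy,
)

omega_meV = wavenumber_to_energy(122.0)  # 122 cm^-1 mode -> ~15 meV
print(f"effective mode: 122 cm^-1 = {omega_meV:.1f} meV, "
      f"T_C = {crossover_temperature(omega_meV):.0f} K")

jp = JortnerParams(H=1e-3, lambda_reorg=0.35, omega_eff=omega_meV)
mp = MarcusParams(H=1e-3, lambda_reorg=0.35)

print(f"{'T (K)':>7} {'Marcus (1/s)':>14} {'Jortner (1/s)':>14} {'ratio':>10}")
for T in [300, 200, 100, 50, 20, 5]:
    m = marcus_forward_rate(0.0, T, mp)
    j = jortner_rate(0.0, T, jp)
    print(f"{T:7.0f} {m:14.3e} {j:14.3e} {j / m:10.2e}")

# The two rates agree at high temperature; below T_C the Marcus rate
# freezes out exponentially while the Jortner rate saturates at its
# zero-point (nuclear-tunneling) plateau -- the ratio diverges.
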