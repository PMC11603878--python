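# Methods

## Transport model

The fiber network is treated as `n_channels` identical, independent 1D
hopping chains of `N_S` sites with spacing δ (so L = N_S·δ). Bias partitions
equally over hops (no site disorder), giving Δ = eV/N_S = eEδ per hop, and
the steady-state current per channel is I = e·[Γ(+Δ) − Γ(−Δ)]. A single
effective carrier per channel is assumed; many-body exclusion and the true
carrier density are absorbed into the prefactor, which is legitimate because
every estimation procedure in the package is shape-based (log-axis fits that
are exactly invariant under rescaling of G — this invariance is itself
tested).

### Rate kernels

**Marcus.** Γ = (H²/ℏ)√(π/λk_BT)·exp(−(λ−Δ)²/4λk_BT). H (eV) enters only as
H²; the default H = 1 meV is a placeholder scale, not a fitted quantity.
The exact forward-minus-backward difference gives the closed-form chain
conductance

G(T, Δ) = g₀·T^(−3/2)·exp(−λ/4k_BT)·exp(−Δ²/4λk_BT)·(2k_BT/Δ)·sinh(Δ/2k_BT),

whose Δ→0 limit is the familiar G = g₀T^(−3/2)exp(−λ/4k_BT). The
exp(−Δ²/4λk_BT) cross term is retained (it is what the algebra produces);
it only matters at fields where Δ² ≳ λk_BT, far above the low-field regime
the fit procedures use. The T^(−3/2) arises as T^(−1/2) from the Marcus
prefactor times the 1/T of linearizing sinh(Δ/2k_BT).

**Jortner (single quantum mode).** With S = λ/ℏ⟨ω⟩, x = ℏ⟨ω⟩/k_BT and
ν = |Δ|/ℏ⟨ω⟩:

Γ(Δ) = (2πH²/ℏ²⟨ω⟩)·exp(−S·coth(x/2))·exp(Δ/2k_BT)·I_ν(S/sinh(x/2)).

Energy conservation at non-integer phonon number uses the modified Bessel
function of real order ν rather than nearest-integer snapping: the rate is
smooth in Δ, and the explicit exp(Δ/2k_BT) factor together with the |Δ|
order makes detailed balance Γ(+Δ)/Γ(−Δ) = exp(Δ/k_BT) exact by
construction. The prefactor 2πH²/ℏ²⟨ω⟩ is the unique normalization for
which the k_BT ≫ ℏ⟨ω⟩ limit reduces *exactly* to the Marcus kernel with the
same (H, λ); this is verified numerically (ratio → 1 monotonically, within
5% at k_BT = 5ℏ⟨ω⟩). At T = 0 the rate becomes the analytic tunneling
expression e^(−S)S^ν/Γ(ν+1) for Δ ≥ 0 and vanishes uphill. Evaluation uses
the exponentially scaled Bessel function so large S and small T neither
overflow nor underflow prematurely.

**Ohmic bath (universal scaling).** I = B₀T^(1+β)·sinh(u/2)·|Γ(1+β/2 +
iu/2π)|², u = eV/(N_S·k_BT). The bath's upper cutoff frequency is not an
explicit parameter: β and B₀ are the effective parameters the curve
exposes. The magnitude is assembled in log space (log-sinh plus twice the
real part of the complex log-gamma), so u up to ~10³ is evaluated without
overflow and the T-independence of I/T^(1+β) at fixed u holds to machine
precision. Asymptotically G ∝ T^β (u ≪ 1) and G ∝ E^β (u ≫ 1).

### Kinetic Monte Carlo oracle

An independent stochastic check of the deterministic current: a single
walker on a periodic biased ring (drift-velocity formulation — a ring
avoids reservoir boundary conventions the chain model never specifies),
with Gillespie sampling of uniform forward/backward rates. The current
estimate is e·(net hops)/(elapsed time), with a standard error from ten
batch means. The batch standard error has t-like tails, so consistency
tests allow occasional nominal 3σ excursions among many draws.

## Reduction of I(V) sweeps

Nondifferential conductance G = [I(+V) − I(−V)]/2V uses the symmetric pair;
a missing partner may be linearly interpolated only when explicitly enabled
(symmetric sweeps are the normal case). The zero-bias conductance is the
OLS slope of I on V in a |V| ≤ 10% of V_max window with a minimum of four
points; if the window holds fewer, it widens to the four samples nearest
zero bias rather than failing (relevant only for coarse sweeps). Detection
handling masks points with |I| below the floor but never deletes them;
reductions are pure functions of immutable traces. E = V/L is flagged as an
indicative upper bound for two-probe data, where contacts drop part of V.

## Estimation procedures

All conductance fits run on log G, matching how such data are analysed
(and weighting decades equally):

- **λ fit:** log G = log g₀ − (3/2)log T − λ/4k_BT on T ≥ 100 K. After
  moving the known T^(−3/2) term across, the problem is linear in
  (log g₀, λ) and is solved exactly by OLS — the residuals minimised are
  identical to the nonlinear formulation's. Grid weighting is uniform in
  the supplied temperatures.
- **Arrhenius fit:** the simplification that drops T^(−3/2); on
  λ-generated data it returns U_A = λ/4 − (3/2)k_B·T̄_eff analytically,
  with T̄_eff an OLS-weighted window temperature.
- **Crossover:** scanning temperatures descending, T_C is the first
  (highest) T where the Arrhenius prediction is 20% below the measured G.
  Absence is a valid outcome (pure-Arrhenius data). Note the detector
  triggers well below ℏ⟨ω⟩/k_B on single-mode-chain curves: the Arrhenius
  line, biased shallow by the −(3/2)k_BT̄ term, over-predicts below its
  window before the tunneling excess overtakes it. For the long-segment
  parameter set (λ = 0.35 eV, ℏ⟨ω⟩ = 15 meV) detection lands near 65 K,
  consistent with the ~75 K crossover reported for measured curves.
- **Power laws:** α from log G–log T OLS on 20–100 K; β from log G–log E
  at the lowest temperature using the upper half of the field range.
- **Universal-scaling fit:** minimises squared residuals of log|I| over
  (log B₀, log N_S, β); B₀ has a closed-form optimum at fixed (N_S, β), so
  initialisation is a coarse grid over β ∈ [2, 12] and N_S log-spaced in
  [10, 10⁴], followed by trust-region refinement. Noise-free
  self-generated data are recovered to ~10⁻⁶. The low-temperature window
  defaults to "below the detected crossover", widened to the four coldest
  sweeps when that leaves fewer than three temperatures.
- **Surface fit:** the Jortner-chain G(T, E) model fitted over
  (scale, λ, ℏ⟨ω⟩, N_S) with L fixed, so N_S is identified by the onset of
  field dependence (Δ = eEL/N_S). ℏ⟨ω⟩ is flagged non-identifiable when
  the data contain no temperatures below the fitted crossover; N_S when
  the surface shows no field response. Model conductances are clamped at
  10⁻²⁸⁰ S before taking logs so underflowed corners of parameter space
  yield large finite residuals instead of NaNs.

## Synthetic data

The generator emulates the structure of cryogenic measurement series:
per-temperature symmetric linear sweeps (41 points), descending temperature
grids (cooldown order), a terminal-bias solve against a series contact
resistance for two-probe mode (bracketed root finding on the fiber
voltage), multiplicative log-normal noise (default 2% — conductances span
decades, so noise is proportional; the floor is the only additive scale),
and masking below a 10⁻¹³ A detection floor. Identical seeds give
byte-identical datasets. Sweep amplitudes respect the E < 2.5 V/μm ceiling
of the measurements being emulated.

Two fixtures mirror the published model curves. The long segment
(L = 240 μm, λ = 0.35 eV, ℏ⟨ω⟩ = 15 meV) uses N_S = L/δ at the default
cofactor spacing, since the site count does not affect its low-field
shape; its currents fall below the detection floor below ~50–60 K,
reproducing the loss of signal seen for long segments. The short segment
(L = 4 μm, λ = 0.16 eV, ℏ⟨ω⟩ = 7.2 meV) uses the published N_S = 200,
implying a 20 nm effective hop length and the strong low-temperature field
dependence that goes with it. The default H = 1 meV puts fixture currents
in the nA range — the analysis is shape-based throughout, so absolute
current scale carries no information. What the generator does *not*
emulate: site-energy disorder, temperature-dependent contacts (a hook
exists), instrument artifacts (thermometer lag, exchange-gas effects), or
inter-chain hopping. Passing tests therefore certify the estimation
machinery against the stated model class, not against every pathology of
real measurements.

## Numerical choices and limitations

- Fixed problem sizes throughout: 30-point temperature grids for the λ
  recoveries, 6 temperatures × 21 biases for scaling fits, 10⁴–10⁵ KMC
  steps — sizes at which every estimator is already well inside its
  asymptotic regime while whole-suite runs stay in seconds.
- The tunneling plateau is asserted over 2–8 K in the deep-frozen regime
  and at fields with Δ ≳ k_BT: in strict linear response G keeps a 1/T
  factor, and at T_C/4 the leading thermal correction exp(−2S·n̄) is still
  ~0.5 for S ≈ 22, so "temperature-independent" is a statement about the
  lowest measured temperatures and the field-assisted regime.
- Chains are fitted per segment; no hierarchical pooling across segments.
- Out of scope by design: ab-initio estimates of H or λ, coherent/band
  transport and mixed hopping-coherent ("cofactor block") models,
  substrate-side heating (the filament term dominates), and Bayesian
  uncertainty quantification.
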