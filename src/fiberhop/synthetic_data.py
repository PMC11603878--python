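"""Synthetic I(V, T) datasets with the structure the analysis assumes.

Generates per-temperature symmetric voltage sweeps from a hopping-chain
model, optionally adds a series contact resistance (two-probe mode, terminal
voltage solved self-consistently), applies multiplicative log-normal noise,
and masks points below a current detection floor — so every reduction and
fitting stage can be exercised end-to-end without measured data.

Two ready-made fixtures mirror the published model curves: a long
(L = 240 um) segment with a 15 meV effective mode and lambda = 0.35 eV, and
a short (L = 4 um) segment with a 7.2 meV mode, lambda = 0.16 eV and
N_S = 200 sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .chain_transport import HoppingChain, chain_current
from .fiber_geometry import SegmentGeometry
from .iv_reduction import IVDataset, IVTrace, apply_detection_floor
from .rate_kernels import JortnerParams

__all__ = [
    "NoiseModel",
    "SyntheticSegmentSpec",
    "generate_ivt",
    "fixture_fig3c",
    "fixture_fig3d",
    "generate_transfer_length_dataset",
]

#: field ceiling (V/um) applied in the measurements being emulated
FIELD_CEILING = 2.5


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description.

    sigma_mult : scale of multiplicative log-normal noise (median-unbiased),
        default 2% — conductances span decades, so noise is proportional.
    detection_floor : instrument current floor in A (default 1e-13).
    seed : RNG seed; identical seeds give byte-identical datasets.
    """

    sigma_mult: float = 0.02
    detection_floor: float = 1.0e-13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_mult < 0:
            raise ValueError("sigma_mult must be >= 0")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be >= 0")


@dataclass(frozen=True)
class SyntheticSegmentSpec:
    """Everything needed to synthesise one segment's I(V, T) series.

    geometry : segment geometry (provides L and the conversion constants).
    chain : hopping-chain transport model generating the fiber current.
    T_grid : temperatures (K), stored descending like a cooldown.
    V_max : maximum sweep bias, a scalar or one value per temperature; must
        respect the E < 2.5 V/um field ceiling.
    probe_mode : "two_probe" adds the series contact resistance R_C.
    contact_resistance : R_C in ohm (two-probe only).
    noise : noise model (multiplicative scale, floor, seed).
    n_bias : points per sweep, symmetric and linear in V.
    """

    geometry: SegmentGeometry
    chain: HoppingChain
    T_grid: Sequence[float]
    V_max: Union[float, Sequence[float]]
    probe_mode: str = "four_probe"
    contact_resistance: float = 0.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_bias: int = 41
    segment_id: str = "synthetic"

    def __post_init__(self) -> None:
        T = np.asarray(self.T_grid, dtype=float)
        if np.any(np.diff(T) > 0):
            object.__setattr__(self, "T_grid", tuple(np.sort(T)[::-1]))
        else:
            object.__setattr__(self, "T_grid", tuple(T))
        vmax = np.broadcast_to(
            np.asarray(self.V_max, dtype=float), (len(self.T_grid),)
        )
        object.__setattr__(self, "V_max", tuple(vmax))
        if np.any(vmax / self.geometry.L > FIELD_CEILING + 1e-12):
            raise ValueError(
                f"V_max violates the field ceiling E < {FIELD_CEILING} V/um"
            )
        if self.probe_mode == "two_probe" and self.contact_resistance < 0:
            raise ValueError("contact_resistance must be >= 0")


def _terminal_current(V_applied: float, T: float, chain, R_C: float) -> float:
    """Current at applied terminal bias with a series contact resistance.

    Solves V_applied = V_fiber + I(V_fiber) R_C for V_fiber by bracketed
    root finding (I is monotone in V).
    """
    if V_applied == 0.0 or R_C == 0.0:
        return float(chain_current(V_applied, T, chain))

    def f(v_f):
        return v_f + chain_current(v_f, T, chain) * R_C - V_applied

    lo, hi = sorted((0.0, V_applied))
    try:
        v_f = brentq(f, lo, hi, xtol=1e-15, rtol=1e-14)
    except ValueError as err:
        raise RuntimeError(
            f"series-resistance solve failed at V = {V_applied}, T = {T}: {err}"
        ) from err
    return float(chain_current(v_f, T, chain))


def generate_ivt(spec: SyntheticSegmentSpec) -> IVDataset:
    """Synthesise the I(V, T) dataset described by `spec`.

    For each temperature, a symmetric linear bias sweep; fiber current from
    the chain model; for two-probe mode the terminal voltage is divided
    self-consistently with the series R_C; multiplicative log-normal noise
    and detection-floor masking are then applied.  Fully deterministic for a
    given spec (seed included).
    """
    rng = np.random.default_rng(spec.noise.seed)
    traces = []
    R_C = spec.contact_resistance if spec.probe_mode == "two_probe" else 0.0
    for T, vmax in zip(spec.T_grid, spec.V_max):
        bias = np.linspace(-vmax, vmax, spec.n_bias)
        current = np.array(
            [_terminal_current(float(v), float(T), spec.chain, R_C) for v in bias]
        )
        if spec.noise.sigma_mult > 0:
            current = current * np.exp(
                spec.noise.sigma_mult * rng.standard_normal(current.shape)
            )
        trace = IVTrace(
            temperature=float(T),
            probe_mode=spec.probe_mode,
            bias=bias,
            current=current,
            segment_length=spec.geometry.L,
            detection_floor=spec.noise.detection_floor,
        )
        traces.append(apply_detection_floor(trace))
    return IVDataset(
        segment_id=spec.segment_id, traces=traces, geometry=spec.geometry
    )


def fixture_fig3c(
    seed: int = 0, noise: float = 0.0, n_bias: int = 41
) -> SyntheticSegmentSpec:
    """Long-segment fixture: Jortner chain, lambda = 0.35 eV, hbar<w> = 15 meV.

    L = 240 um with N_S = L/delta at the default cofactor spacing (the site
    count does not change the shape of the low-field G(T) curves).  Sweep
    amplitudes keep E well below the ceiling; currents drop below the
    detection floor at the lowest temperatures, as for a long segment.
    """
    geom = SegmentGeometry(L=240.0)
    n_sites = int(round(geom.L * 1e3 / geom.delta_site))
    chain = HoppingChain(
        n_sites=n_sites,
        delta_site=geom.delta_site,
        n_channels=geom.N_F * geom.N_C,
        rate_model=JortnerParams(H=1.0e-3, lambda_reorg=0.35, omega_eff=15.0),
    )
    T_grid = np.r_[np.arange(300.0, 95.0, -15.0), np.arange(90.0, 4.0, -10.0), 5.0]
    return SyntheticSegmentSpec(
        geometry=geom,
        chain=chain,
        T_grid=T_grid,
        V_max=24.0,  # E = 0.1 V/um
        noise=NoiseModel(sigma_mult=noise, seed=seed),
        n_bias=n_bias,
        segment_id="fig3c_long",
    )


def fixture_fig3d(
    seed: int = 0, noise: float = 0.0, n_bias: int = 41
) -> SyntheticSegmentSpec:
    """Short-segment fixture: lambda = 0.16 eV, hbar<w> = 7.2 meV, N_S = 200.

    L = 4 um, so the 200 sites imply a 20 nm effective hop length and a
    strong field dependence of G at low temperature.
    """
    geom = SegmentGeometry(L=4.0)
    chain = HoppingChain(
        n_sites=200,
        delta_site=geom.L * 1e3 / 200.0,
        n_channels=geom.N_F * geom.N_C,
        rate_model=JortnerParams(H=1.0e-3, lambda_reorg=0.16, omega_eff=7.2),
    )
    T_grid = np.r_[np.arange(300.0, 95.0, -15.0), np.arange(90.0, 4.0, -10.0), 5.0]
    return SyntheticSegmentSpec(
        geometry=geom,
        chain=chain,
        T_grid=T_grid,
        V_max=8.0,  # E = 2 V/um
        noise=NoiseModel(sigma_mult=noise, seed=seed),
        n_bias=n_bias,
        segment_id="fig3d_short",
    )


def generate_transfer_length_dataset(
    sigma: float,
    geom: Optional[SegmentGeometry] = None,
    electrode_positions_um: Sequence[float] = (50, 100, 200, 400, 800, 1600),
    contact_offsets_ohm: Union[float, Sequence[float]] = 0.0,
    noise: float = 0.0,
    seed: int = 0,
):
    """Resistance versus probed length for a homogeneous Ohmic filament.

    R(L) = L / (sigma N_F A_F) + offset, with sigma in S/cm; optional
    per-electrode contact offsets (shift the intercept, not the slope) and
    multiplicative noise.  Returns (L_um, R_ohm) arrays.
    """
    geom = geom or SegmentGeometry()
    L_um = np.asarray(electrode_positions_um, dtype=float)
    if L_um.size < 3:
        raise ValueError("need >= 3 electrode positions")
    sigma_SI = sigma * 100.0
    R = L_um * 1e-6 / (sigma_SI * geom.N_F * geom.A_F)
    R = R + np.broadcast_to(np.asarray(contact_offsets_ohm, float), R.shape)
    if noise > 0:
        rng = np.random.default_rng(seed)
        R = R * np.exp(noise * rng.standard_normal(R.shape))
    return L_um, R
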