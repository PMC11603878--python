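"""Single-hop electron-transfer rate laws.

Three kernels of increasing sophistication describe one hopping step between
neighbouring charge-carrier sites:

* classical nonadiabatic (Marcus) transfer over a thermal barrier,
* a single effective quantum vibrational mode (Jortner), which keeps the
  transfer alive at cryogenic temperatures through nuclear tunneling,
* a multimode Ohmic-bath model whose finite-bias current obeys a universal
  I(V, T) scaling law (sinh times squared complex gamma).

All kernels satisfy detailed balance Gamma(+D)/Gamma(-D) = exp(D/k_B T)
exactly, and the Jortner kernel reduces to the Marcus kernel for
k_B T >> hbar<w> with the same electronic coupling and reorganization energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ive, loggamma

from .constants import CONST, wavenumber_to_energy

__all__ = [
    "MarcusParams",
    "JortnerParams",
    "OhmicBathParams",
    "wavenumber_to_energy",
    "marcus_forward_rate",
    "jortner_rate",
    "crossover_temperature",
    "ohmic_universal_current",
]


@dataclass(frozen=True)
class MarcusParams:
    """Classical Marcus kernel parameters.

    H : electronic coupling between neighbouring sites (eV).  Enters only as
        a multiplicative H^2 prefactor, so shape-based fits may leave it at
        the default (arbitrary-prefactor mode).
    lambda_reorg : reorganization energy lambda (eV); sets the zero-bias
        activation barrier lambda/4.
    """

    H: float = 1.0e-3
    lambda_reorg: float = 0.27

    def __post_init__(self) -> None:
        if self.H <= 0:
            raise ValueError(f"electronic coupling H must be > 0, got {self.H}")
        if self.lambda_reorg <= 0:
            raise ValueError(
                f"reorganization energy must be > 0, got {self.lambda_reorg}"
            )


@dataclass(frozen=True)
class JortnerParams:
    """Single-quantum-mode (Jortner) kernel parameters.

    H : electronic coupling (eV).
    lambda_reorg : reorganization energy lambda (eV).
    omega_eff : effective vibrational quantum hbar<w> (meV).

    The Huang-Rhys factor S = lambda / hbar<w> measures electron-vibration
    coupling strength; `n_bar(T)` is the Bose occupancy of the mode.
    """

    H: float = 1.0e-3
    lambda_reorg: float = 0.35
    omega_eff: float = 15.0

    def __post_init__(self) -> None:
        if self.H <= 0:
            raise ValueError(f"electronic coupling H must be > 0, got {self.H}")
        if self.lambda_reorg <= 0:
            raise ValueError(
                f"reorganization energy must be > 0, got {self.lambda_reorg}"
            )
        if self.omega_eff <= 0:
            raise ValueError(f"omega_eff must be > 0, got {self.omega_eff}")

    @property
    def huang_rhys(self) -> float:
        """S = lambda / hbar<w> (dimensionless)."""
        return self.lambda_reorg / (self.omega_eff * 1e-3)

    def n_bar(self, T: float) -> float:
        """Thermal occupancy of the effective mode; 0 at T = 0."""
        if T < 0:
            raise ValueError(f"temperature must be >= 0, got {T}")
        if T == 0:
            return 0.0
        x = self.omega_eff * 1e-3 / (CONST.k_B_eV * T)
        return 1.0 / math.expm1(x)


@dataclass(frozen=True)
class OhmicBathParams:
    """Multimode Ohmic-bath (universal-scaling) parameters.

    beta : dimensionless bath-coupling exponent; G ~ T^beta at low bias and
        G ~ E^beta at low temperature.
    B0 : current prefactor (A * K^-(1+beta)) for the whole measured segment.

    The bath's upper cutoff frequency is not an explicit parameter: beta and
    B0 are the effective parameters the scaling curve exposes.
    """

    beta: float = 6.0
    B0: float = 1.0e-12

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.B0 <= 0:
            raise ValueError(f"B0 must be > 0, got {self.B0}")


def marcus_forward_rate(delta, T, p: MarcusParams):
    """Classical nonadiabatic transfer rate (s^-1).

    Gamma_F = (H^2/hbar) sqrt(pi / (lambda k_B T))
              * exp(-(lambda - Delta)^2 / (4 lambda k_B T))

    Parameters
    ----------
    delta : driving force Delta in eV (energy gained by the hop); may be an
        array.  Negative values give the backward rate.
    T : temperature in K, > 0.
    p : Marcus parameters.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be > 0 for the Marcus kernel")
    delta = np.asarray(delta, dtype=float)
    lam = p.lambda_reorg
    kT = CONST.k_B_eV * T
    pref = (p.H**2 / CONST.hbar_eVs) * np.sqrt(np.pi / (lam * kT))
    out = pref * np.exp(-((lam - delta) ** 2) / (4.0 * lam * kT))
    return out if out.ndim else float(out)


def jortner_rate(delta, T, p: JortnerParams):
    """Single-mode multiphonon (Jortner) transfer rate (s^-1).

    Gamma(Delta) = (2 pi H^2 / (hbar^2 <w>)) * exp(-S coth(x/2))
                   * exp(Delta / 2 k_B T) * I_nu(S / sinh(x/2))

    with x = hbar<w>/k_B T, Huang-Rhys factor S and modified Bessel function
    I_nu of real order nu = |Delta|/hbar<w>.  The |Delta| order together with
    the explicit exp(Delta/2k_BT) factor keeps detailed balance exact for
    non-integer phonon numbers while remaining smooth in Delta.

    T = 0 is allowed: the rate becomes the temperature-independent
    nuclear-tunneling expression e^-S S^nu / Gamma(nu+1) for Delta >= 0 and
    vanishes for Delta < 0.  For k_B T >> hbar<w> the kernel reduces to
    `marcus_forward_rate` with the same (H, lambda).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("temperature must be >= 0 for the Jortner kernel")
    delta = np.asarray(delta, dtype=float)
    delta, T = np.broadcast_arrays(delta, T)
    hw = p.omega_eff * 1e-3  # eV
    S = p.huang_rhys
    nu = np.abs(delta) / hw
    C = 2.0 * np.pi * p.H**2 / (CONST.hbar_eVs**2 * (hw / CONST.hbar_eVs))
    # C = 2*pi*H^2/(hbar^2 * omega) with omega in rad/s -> s^-1

    out = np.empty_like(delta, dtype=float)
    zero_T = T == 0

    if np.any(zero_T):
        d0 = delta[zero_T]
        n0 = nu[zero_T]
        with np.errstate(over="ignore"):
            r0 = np.where(
                d0 >= 0,
                C * np.exp(-S + n0 * math.log(S) - _lgamma(n0 + 1.0)),
                0.0,
            )
        out[zero_T] = r0

    pos = ~zero_T
    if np.any(pos):
        Tp = T[pos]
        dp = delta[pos]
        np_nu = nu[pos]
        kT = CONST.k_B_eV * Tp
        x = hw / kT
        half = x / 2.0
        z = S / np.sinh(half)
        # exponent assembled in log space: ive(nu, z) = exp(-z) I_nu(z)
        log_term = -S / np.tanh(half) + z + dp / (2.0 * kT)
        bess = ive(np_nu, z)
        with np.errstate(divide="ignore"):
            log_bess = np.where(bess > 0, np.log(np.where(bess > 0, bess, 1.0)), -np.inf)
        out[pos] = C * np.exp(log_term + log_bess)

    return out if out.ndim else float(out)


def _lgamma(v):
    return np.vectorize(math.lgamma, otypes=[float])(v)


def crossover_temperature(omega_eff: float) -> float:
    """Crossover temperature T_C = hbar<w>/k_B (K) for a mode quantum in meV.

    Above T_C the effective mode is thermally excited and transport is
    Arrhenius-like; below it nuclear tunneling keeps the rate finite.
    """
    if omega_eff < 0:
        raise ValueError(f"omega_eff must be >= 0, got {omega_eff}")
    return omega_eff * 1e-3 / CONST.k_B_eV


def ohmic_universal_current(V, T, N_S: float, p: OhmicBathParams):
    """Universal-scaling current (A) of the multimode Ohmic-bath model.

    With normalized bias u = eV / (N_S k_B T),

        I = B0 * T^(1+beta) * sinh(u/2) * |Gamma(1 + beta/2 + i u/(2 pi))|^2

    so that I/T^(1+beta) is a function of u alone (scaling collapse).  Odd in
    V; G = I/V goes as T^beta at small u and as E^beta at large u.
    Evaluated in log space so that extreme u neither overflow the sinh nor
    underflow the gamma magnitude.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be > 0 for the Ohmic-bath model")
    if N_S < 1:
        raise ValueError(f"N_S must be >= 1, got {N_S}")
    V = np.asarray(V, dtype=float)
    V, T = np.broadcast_arrays(V, T)
    u = V / (N_S * CONST.k_B_eV * T)
    au = np.abs(u)
    # log sinh(au/2), stable for large argument
    with np.errstate(divide="ignore"):
        log_sinh = np.where(
            au > 0,
            au / 2.0 + np.log1p(-np.exp(-np.where(au > 0, au, 1.0))) - math.log(2.0),
            -np.inf,
        )
    lg = loggamma(1.0 + p.beta / 2.0 + 1j * au / (2.0 * np.pi))
    log_mag = (1.0 + p.beta) * np.log(T) + log_sinh + 2.0 * np.real(lg)
    out = np.sign(u) * p.B0 * np.exp(log_mag)
    out = np.where(u == 0, 0.0, out)
    return out if out.ndim else float(out)
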