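"""Parallel 1D hopping-chain transport model.

The conductive fiber network is modelled as `n_channels` identical
one-dimensional chains of N_S charge-carrier sites with center-to-center
spacing delta.  A terminal bias V is shared equally over the hops, giving a
per-hop driving force Delta = eV/N_S = eE*delta, and the net per-channel
current is e*(Gamma(+Delta) - Gamma(-Delta)) with the chain's single-hop
rate kernel.

For the Marcus kernel the resulting nondifferential conductance has the
closed form

    G(T, Delta) = g0 T^(-3/2) exp(-lambda/4k_BT) exp(-Delta^2/4 lambda k_BT)
                  * (2 k_B T / Delta) sinh(Delta / 2 k_B T)

which reduces at low field to G = g0 T^(-3/2) exp(-lambda/4k_BT).  A kinetic
Monte Carlo walker on a biased ring provides an independent stochastic check
of the deterministic current.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .constants import CONST
from .rate_kernels import (
    JortnerParams,
    MarcusParams,
    OhmicBathParams,
    jortner_rate,
    marcus_forward_rate,
    ohmic_universal_current,
)

RateModel = Union[MarcusParams, JortnerParams, OhmicBathParams]

__all__ = [
    "HoppingChain",
    "ConductanceSurface",
    "site_driving_force",
    "hop_rate",
    "chain_current",
    "low_field_conductance",
    "marcus_chain_conductance_closed_form",
    "kmc_chain_oracle",
    "conductance_surface",
]


@dataclass(frozen=True)
class HoppingChain:
    """A parallel set of identical 1D hopping chains.

    n_sites : number of hopping sites N_S per chain.
    delta_site : center-to-center site spacing delta (nm).
    n_channels : number of parallel chains (fibers x channels per fiber).
    rate_model : single-hop kernel parameters (Marcus, Jortner or Ohmic bath).
    """

    n_sites: int
    delta_site: float
    n_channels: int = 1
    rate_model: RateModel = field(default_factory=MarcusParams)

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.delta_site <= 0:
            raise ValueError(f"delta_site must be > 0, got {self.delta_site}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")

    @property
    def length_um(self) -> float:
        """Chain length L = N_S * delta in micrometers."""
        return self.n_sites * self.delta_site * 1e-3


def site_driving_force(V, n_sites: int):
    """Per-hop driving force Delta = eV/N_S in eV (equal bias partition).

    Numerically Delta[eV] = V[volt]/N_S; identical to e*E*delta with
    E = V/L and L = N_S*delta.
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    return np.asarray(V, dtype=float) / n_sites if np.ndim(V) else V / n_sites


def hop_rate(delta, T, model: RateModel):
    """Dispatch the single-hop rate Gamma(Delta, T) for a Marcus or Jortner
    kernel (the Ohmic-bath model has no single-hop rate; its current is the
    universal scaling law)."""
    if isinstance(model, MarcusParams):
        return marcus_forward_rate(delta, T, model)
    if isinstance(model, JortnerParams):
        return jortner_rate(delta, T, model)
    raise TypeError(
        "hop_rate is defined for Marcus and Jortner kernels; the Ohmic-bath "
        "model enters through ohmic_universal_current"
    )


def chain_current(V, T, chain: HoppingChain):
    """Total current (A) through the parallel chains at terminal bias V.

    Per channel I = e*(Gamma(+Delta) - Gamma(-Delta)) with Delta = eV/N_S;
    antisymmetric in V.  For an Ohmic-bath rate model the current is the
    universal scaling expression for the whole segment (B0 absorbs the
    channel count).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be > 0")
    if isinstance(chain.rate_model, OhmicBathParams):
        return ohmic_universal_current(V, T, chain.n_sites, chain.rate_model)
    delta = site_driving_force(V, chain.n_sites)
    net = hop_rate(delta, T, chain.rate_model) - hop_rate(-np.asarray(delta), T, chain.rate_model)
    out = CONST.e * chain.n_channels * net
    return out if np.ndim(out) else float(out)


def low_field_conductance(T, g0: float, lambda_reorg: float):
    """Low-field chain conductance G = g0 T^(-3/2) exp(-lambda/4k_BT) (S).

    lambda_reorg in eV; lambda_reorg = 0 gives the bare T^(-3/2) law.
    The low-field limit carries no field dependence by construction.
    """
    T = np.asarray(T, dtype=float)
    out = g0 * T ** (-1.5) * np.exp(-lambda_reorg / (4.0 * CONST.k_B_eV * T))
    return out if out.ndim else float(out)


def marcus_g0(chain: HoppingChain) -> float:
    """Low-field prefactor g0 (S K^{3/2}) implied by the chain's Marcus kernel.

    Obtained by linearizing the exact forward-minus-backward current, so the
    closed form and `chain_current` agree without any free constant.
    """
    p = chain.rate_model
    if not isinstance(p, MarcusParams):
        raise TypeError("marcus_g0 requires a Marcus rate model")
    lam = p.lambda_reorg
    return (
        CONST.e
        * chain.n_channels
        * p.H**2
        / (CONST.hbar_eVs * chain.n_sites)
        * np.sqrt(np.pi / lam)
        * CONST.k_B_eV ** (-1.5)
    )


def marcus_chain_conductance_closed_form(E, T, chain: HoppingChain):
    """Closed-form nondifferential conductance G(T, E) (S) of a Marcus chain.

    E is the electric field in V/um; Delta = e*E*delta.  Valid for
    Delta < lambda (a warning is emitted outside that regime).  Reduces to
    `low_field_conductance` as Delta -> 0 and matches chain_current/V exactly
    (the exp(-Delta^2/4 lambda k_B T) cross term is retained).
    """
    p = chain.rate_model
    if not isinstance(p, MarcusParams):
        raise TypeError("closed form requires a Marcus rate model")
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be > 0")
    E = np.asarray(E, dtype=float)
    delta = E * chain.delta_site * 1e-3  # eV
    lam = p.lambda_reorg
    if np.any(np.abs(delta) >= lam):
        warnings.warn(
            "driving force Delta >= lambda: outside the stated validity "
            "regime of the sinh closed form",
            stacklevel=2,
        )
    kT = CONST.k_B_eV * T
    g0 = marcus_g0(chain)
    base = g0 * T ** (-1.5) * np.exp(-lam / (4.0 * kT)) * np.exp(
        -(delta**2) / (4.0 * lam * kT)
    )
    x = delta / (2.0 * kT)
    sinhc = np.where(x == 0, 1.0, np.sinh(np.where(x == 0, 1.0, x)) / np.where(x == 0, 1.0, x))
    out = base * sinhc
    return out if out.ndim else float(out)


def kmc_chain_oracle(V, T, chain: HoppingChain, steps: int = 10_000, seed: int = 0):
    """Kinetic Monte Carlo estimate of the chain current (A) with its s.e.

    Simulates a single walker on a periodic biased ring with uniform forward
    and backward rates from the chain's kernel (drift-velocity formulation:
    no reservoir boundaries).  Current = e * n_channels * net hops / elapsed
    time; the standard error comes from ten batch means.

    Returns (current, standard_error).
    """
    if steps < 10_000:
        raise ValueError("steps must be >= 1e4 for a usable estimate")
    delta = site_driving_force(V, chain.n_sites)
    gf = float(hop_rate(delta, T, chain.rate_model))
    gb = float(hop_rate(-delta, T, chain.rate_model))
    total = gf + gb
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate chain: total hopping rate is zero")
    rng = np.random.default_rng(seed)
    n_batches = 10
    per = steps // n_batches
    rates = np.empty(n_batches)
    for b in range(n_batches):
        direction = rng.random(per) < gf / total
        hops = np.where(direction, 1, -1).sum()
        elapsed = rng.exponential(1.0 / total, size=per).sum()
        rates[b] = hops / elapsed
    scale = CONST.e * chain.n_channels
    current = scale * rates.mean()
    stderr = scale * rates.std(ddof=1) / np.sqrt(n_batches)
    return current, stderr


@dataclass
class ConductanceSurface:
    """Nondifferential conductance G = I/V on a (temperature, field) grid.

    T_grid : temperatures in K, stored descending (cooldown order).
    E_grid : electric fields in V/um.
    G : conductance (S), shape (len(T_grid), len(E_grid)); NaN where masked
        (e.g. below a detection floor).
    """

    T_grid: np.ndarray
    E_grid: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        self.E_grid = np.asarray(self.E_grid, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape != (self.T_grid.size, self.E_grid.size):
            raise ValueError("G must have shape (n_T, n_E)")
        if np.any(np.diff(self.T_grid) > 0):
            order = np.argsort(self.T_grid)[::-1]
            self.T_grid = self.T_grid[order]
            self.G = self.G[order]

    @property
    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.G)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: temperature_K, field_V_per_um, conductance_S, masked."""
        TT, EE = np.meshgrid(self.T_grid, self.E_grid, indexing="ij")
        return pd.DataFrame(
            {
                "temperature_K": TT.ravel(),
                "field_V_per_um": EE.ravel(),
                "conductance_S": self.G.ravel(),
                "masked": ~np.isfinite(self.G.ravel()),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConductanceSurface":
        T_grid = np.sort(df["temperature_K"].unique())[::-1]
        E_grid = np.sort(df["field_V_per_um"].unique())
        G = np.full((T_grid.size, E_grid.size), np.nan)
        ti = {t: i for i, t in enumerate(T_grid)}
        ei = {e: j for j, e in enumerate(E_grid)}
        for _, row in df.iterrows():
            if not row.get("masked", False):
                G[ti[row["temperature_K"]], ei[row["field_V_per_um"]]] = row[
                    "conductance_S"
                ]
        return cls(T_grid, E_grid, G)


def conductance_surface(chain: HoppingChain, T_grid, E_grid) -> ConductanceSurface:
    """Evaluate G(T, E) = I/V for the chain over the given grids.

    E_grid is in V/um; the bias per chain is V = E * L with L = N_S*delta.
    Ohmic-bath chains delegate to the universal scaling current.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    E_grid = np.asarray(E_grid, dtype=float)
    if T_grid.size == 0 or E_grid.size == 0:
        raise ValueError("temperature and field grids must be nonempty")
    L = chain.length_um
    V_grid = E_grid * L
    if np.any(V_grid == 0):
        raise ValueError("E = 0 has no nondifferential conductance; use E > 0")
    G = np.empty((T_grid.size, E_grid.size))
    for i, T in enumerate(T_grid):
        I = chain_current(V_grid, float(T), chain)
        G[i] = I / V_grid
    return ConductanceSurface(T_grid, E_grid, G)
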