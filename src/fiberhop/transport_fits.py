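"""Parameter-estimation procedures for hopping-transport data.

High-temperature fits extract the reorganization energy lambda (log G versus
1/T with the T^(-3/2) prefactor retained) and the simplified Arrhenius
activation energy U_A; a descending-temperature scan locates the crossover
where measured conductance exceeds the Arrhenius prediction by 20%.
Low-temperature behaviour is summarised by power-law exponents alpha
(G ~ T^alpha at low bias) and beta (G ~ E^beta at the lowest temperature),
and by the three-parameter (B0, N_S, beta) universal-scaling fit that
collapses I(V, T) onto a single master curve of I/T^(1+beta) versus
u = eV/(N_S k_B T).  A full G(T, E) surface can also be fitted with the
single-mode (Jortner) chain model.

All conductance fits run on log G, which matches the estimation procedures
and weighs the decades of G equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .chain_transport import ConductanceSurface, HoppingChain, conductance_surface
from .constants import CONST
from .rate_kernels import (
    JortnerParams,
    OhmicBathParams,
    crossover_temperature,
    ohmic_universal_current,
)

__all__ = [
    "ArrheniusFit",
    "MarcusFit",
    "PowerLawFit",
    "ScalingFit",
    "CrossoverResult",
    "fit_marcus_lambda",
    "fit_arrhenius",
    "detect_crossover",
    "fit_power_law_temperature",
    "fit_power_law_field",
    "fit_universal_scaling",
    "scaling_collapse",
    "fit_chain_model",
]


@dataclass(frozen=True)
class ArrheniusFit:
    """G = G_ref exp(-U_A / k_B T): activation energy in meV."""

    U_A_meV: float
    G_ref: float
    r_squared: float
    T_range: Tuple[float, float]

    def predict(self, T):
        T = np.asarray(T, dtype=float)
        return self.G_ref * np.exp(-self.U_A_meV * 1e-3 / (CONST.k_B_eV * T))


@dataclass(frozen=True)
class MarcusFit:
    """G = g0 T^(-3/2) exp(-lambda/4 k_B T): reorganization energy in meV."""

    lambda_meV: float
    g0: float
    residual_norm: float
    T_range: Tuple[float, float]

    def predict(self, T):
        T = np.asarray(T, dtype=float)
        return (
            self.g0
            * T ** (-1.5)
            * np.exp(-self.lambda_meV * 1e-3 / (4.0 * CONST.k_B_eV * T))
        )


@dataclass(frozen=True)
class PowerLawFit:
    """G = prefactor * x^exponent fitted on log-log axes."""

    exponent: float
    prefactor: float
    abscissa_range: Tuple[float, float]
    r_squared: float


@dataclass(frozen=True)
class ScalingFit:
    """Universal-scaling parameters (B0, N_S, beta) with collapse residual."""

    B0: float
    N_S: float
    beta: float
    collapse_residual: float
    points_per_temperature: Dict[float, int] = field(default_factory=dict)


@dataclass(frozen=True)
class CrossoverResult:
    """Detected crossover temperature (None if the data stay Arrhenius)."""

    T_C: Optional[float]
    deviation: Dict[float, float] = field(default_factory=dict)


def _clean(T, G, T_min=None, T_max=None):
    T = np.asarray(T, dtype=float)
    G = np.asarray(G, dtype=float)
    ok = np.isfinite(T) & np.isfinite(G) & (G > 0)
    if T_min is not None:
        ok &= T >= T_min
    if T_max is not None:
        ok &= T <= T_max
    return T[ok], G[ok]


def fit_marcus_lambda(T, G, T_min: float = 100.0) -> MarcusFit:
    """Fit G = g0 T^(-3/2) exp(-lambda/4 k_B T) on log G versus 1/T.

    After moving the known T^(-3/2) term to the left-hand side the model is
    linear in (log g0, lambda), so the least-squares problem is solved
    exactly; the residuals minimised are identical to those of a nonlinear
    fit of log G.  Requires >= 6 unmasked points with T >= T_min.
    """
    T, G = _clean(T, G, T_min=T_min)
    if T.size < 6:
        raise ValueError(
            f"need >= 6 unmasked points with T >= {T_min} K, got {T.size}"
        )
    x = 1.0 / T
    y = np.log(G) + 1.5 * np.log(T)
    slope, intercept = np.polyfit(x, y, 1)
    lam_eV = -4.0 * CONST.k_B_eV * slope
    resid = y - (slope * x + intercept)
    return MarcusFit(
        lambda_meV=lam_eV * 1e3,
        g0=float(np.exp(intercept)),
        residual_norm=float(np.sqrt(np.mean(resid**2))),
        T_range=(float(T.min()), float(T.max())),
    )


def fit_arrhenius(T, G, T_min: float = 100.0) -> ArrheniusFit:
    """Simplified fit G = G_ref exp(-U_A/k_B T) (T^(-3/2) term dropped).

    Linear least squares of log G on 1/T; U_A = -slope * k_B.
    """
    T, G = _clean(T, G, T_min=T_min)
    if T.size < 6:
        raise ValueError(
            f"need >= 6 unmasked points with T >= {T_min} K, got {T.size}"
        )
    x = 1.0 / T
    y = np.log(G)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return ArrheniusFit(
        U_A_meV=-slope * CONST.k_B_eV * 1e3,
        G_ref=float(np.exp(intercept)),
        r_squared=1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0,
        T_range=(float(T.min()), float(T.max())),
    )


def detect_crossover(
    T, G, arrhenius: ArrheniusFit, threshold: float = 0.20
) -> CrossoverResult:
    """Locate the crossover out of the Arrhenius regime.

    Scanning temperatures in descending order, the crossover T_C is the
    first (highest) temperature at which the Arrhenius prediction falls
    `threshold` (default 20%) below the measured conductance, i.e.
    G_fit < (1 - threshold) * G_measured.  Absence of such a temperature is
    a valid result (T_C = None): the data are Arrhenius throughout.
    """
    T, G = _clean(T, G)
    order = np.argsort(T)[::-1]
    T, G = T[order], G[order]
    G_fit = arrhenius.predict(T)
    deviation = {float(t): float(1.0 - gf / g) for t, g, gf in zip(T, G, G_fit)}
    below = G_fit < (1.0 - threshold) * G
    if not below.any():
        return CrossoverResult(T_C=None, deviation=deviation)
    return CrossoverResult(T_C=float(T[np.argmax(below)]), deviation=deviation)


def fit_power_law_temperature(
    T, G, T_range: Tuple[float, float] = (20.0, 100.0)
) -> PowerLawFit:
    """Exponent alpha of G ~ T^alpha over a low-temperature window."""
    T, G = _clean(T, G, T_min=T_range[0], T_max=T_range[1])
    if T.size < 5:
        raise ValueError(f"need >= 5 points in T range {T_range}, got {T.size}")
    return _loglog_fit(T, G)


def fit_power_law_field(E, G) -> PowerLawFit:
    """Exponent beta of G ~ E^beta at fixed (lowest) temperature."""
    E, G = _clean(E, G)
    if E.size < 3:
        raise ValueError(f"need >= 3 field points, got {E.size}")
    return _loglog_fit(E, G)


def _loglog_fit(x, y) -> PowerLawFit:
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    return PowerLawFit(
        exponent=float(slope),
        prefactor=float(np.exp(intercept)),
        abscissa_range=(float(x.min()), float(x.max())),
        r_squared=1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0,
    )


# ---------------------------------------------------------------------------
# Universal-scaling (B0, N_S, beta) fit


def _scaling_logI(V, T, N_S, beta):
    """log |I| of the universal curve with B0 = 1."""
    I = ohmic_universal_current(V, T, N_S, OhmicBathParams(beta=beta, B0=1.0))
    return np.log(np.abs(I))


def fit_universal_scaling(
    T, V, I, T_max: Optional[float] = None, beta_grid=None, N_S_grid=None
) -> ScalingFit:
    """Three-parameter fit of I(V, T) to the universal scaling curve.

    Minimises squared residuals of log |I| against
    B0 T^(1+beta) sinh(u/2) |Gamma(1+beta/2 + i u/2pi)|^2, u = eV/(N_S k_B T),
    over (B0, N_S, beta).  Initialisation is a coarse grid search over beta
    and log-spaced N_S (B0 has a closed-form optimum on log axes), followed
    by a Levenberg-Marquardt style refinement in (log B0, log N_S, beta).

    Arrays T, V, I are per-point (flattened sweeps).  Only points from >= 3
    distinct temperatures (each with >= 5 nonzero-bias points) below T_max
    are used.
    """
    T = np.asarray(T, dtype=float)
    V = np.asarray(V, dtype=float)
    I = np.asarray(I, dtype=float)
    ok = np.isfinite(T) & np.isfinite(V) & np.isfinite(I) & (V != 0) & (I * V > 0)
    if T_max is not None:
        ok &= T <= T_max
    T, V, I = T[ok], np.abs(V[ok]), np.abs(I[ok])
    temps, counts = np.unique(T, return_counts=True)
    per_T = {float(t): int(c) for t, c in zip(temps, counts)}
    good = counts >= 5
    if good.sum() < 3:
        raise ValueError(
            "universal-scaling fit needs >= 3 temperatures with >= 5 bias "
            f"points each; got {int(good.sum())}"
        )
    y = np.log(I)

    if beta_grid is None:
        beta_grid = np.linspace(2.0, 12.0, 21)
    if N_S_grid is None:
        N_S_grid = np.geomspace(10.0, 1.0e4, 31)

    best = None
    for beta in beta_grid:
        for ns in N_S_grid:
            m = _scaling_logI(V, T, ns, beta)
            logB0 = float(np.mean(y - m))
            rss = float(np.sum((y - m - logB0) ** 2))
            if best is None or rss < best[0]:
                best = (rss, logB0, ns, beta)

    _, logB0, ns0, beta0 = best

    def resid(p):
        logB0_, logNS_, beta_ = p
        return y - (logB0_ + _scaling_logI(V, T, np.exp(logNS_), beta_))

    sol = least_squares(
        resid,
        x0=[logB0, np.log(ns0), beta0],
        bounds=([-np.inf, 0.0, 0.1], [np.inf, np.log(1e7), 30.0]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        warnings.warn(f"universal-scaling refinement: {sol.message}", stacklevel=2)
    logB0_, logNS_, beta_ = sol.x
    return ScalingFit(
        B0=float(np.exp(logB0_)),
        N_S=float(np.exp(logNS_)),
        beta=float(beta_),
        collapse_residual=float(np.sqrt(np.mean(sol.fun**2))),
        points_per_temperature=per_T,
    )


def scaling_collapse(T, V, I, fit: ScalingFit):
    """Transform I(V, T) points to collapse coordinates and measure spread.

    Returns (u, y, spread) with u = eV/(N_S k_B T), y = I/T^(1+beta), and
    spread the RMS scatter of log10 y about the fitted master curve.
    """
    T = np.asarray(T, dtype=float)
    V = np.asarray(V, dtype=float)
    I = np.asarray(I, dtype=float)
    u = V / (fit.N_S * CONST.k_B_eV * T)
    y = I / T ** (1.0 + fit.beta)
    model = ohmic_universal_current(
        V, T, fit.N_S, OhmicBathParams(beta=fit.beta, B0=fit.B0)
    ) / T ** (1.0 + fit.beta)
    ok = (y * model > 0) & np.isfinite(y)
    spread = float(
        np.sqrt(np.mean((np.log10(np.abs(y[ok])) - np.log10(np.abs(model[ok]))) ** 2))
    )
    return u, y, spread


# ---------------------------------------------------------------------------
# Full G(T, E) surface fit with the single-mode (Jortner) chain


def fit_chain_model(
    surface: ConductanceSurface,
    template: HoppingChain,
    lambda_bounds: Tuple[float, float] = (0.02, 1.5),
    omega_bounds: Tuple[float, float] = (1.0, 60.0),
):
    """Fit a Jortner hopping chain to a measured G(T, E) surface.

    Adjusts (scale, lambda, hbar<w>, N_S) by nonlinear least squares on
    log G.  The chain length L is fixed by the template (L = N_S * delta),
    so N_S sets the per-hop field drop Delta = e E L / N_S: the onset of
    field dependence identifies N_S.  The overall scale absorbs H^2 and the
    channel count (shape-based fit).

    Returns a dict with lambda_eV, omega_eff_meV, N_S, scale, residual_norm
    and identifiability flags: omega is flagged non-identifiable when the
    data contain no temperatures below the fitted crossover, N_S when the
    surface shows no field dependence.
    """
    L = template.length_um
    Tg, Eg = surface.T_grid, surface.E_grid
    ok = np.isfinite(surface.G)
    if ok.sum() < 8:
        raise ValueError("need >= 8 unmasked surface points")
    logG = np.log(surface.G[ok])

    def model_logG(lam, hw, ns):
        chain = HoppingChain(
            n_sites=max(int(round(ns)), 1),
            delta_site=L / ns * 1e3,  # nm, keeps L fixed
            n_channels=template.n_channels,
            rate_model=JortnerParams(
                H=1e-3, lambda_reorg=lam, omega_eff=hw
            ),
        )
        surf = conductance_surface(chain, Tg, Eg)
        # clamp underflowed model conductances so log residuals stay finite
        return np.log(np.clip(surf.G[ok], 1e-280, None))

    def resid(p):
        lam, log_hw, log_ns = p
        m = model_logG(lam, np.exp(log_hw), np.exp(log_ns))
        return (logG - m) - np.mean(logG - m)  # scale has closed-form optimum

    # initialisation: lambda from the high-T window, coarse grids for the rest
    try:
        lam0 = fit_marcus_lambda(
            np.repeat(Tg, Eg.size)[ok.ravel()],
            surface.G[ok],
            T_min=100.0,
        ).lambda_meV * 1e-3
        lam0 = float(np.clip(lam0, *lambda_bounds))
    except ValueError:
        lam0 = 0.25
    best = None
    for hw in np.geomspace(omega_bounds[0] * 1.2, omega_bounds[1] * 0.8, 8):
        for ns in np.geomspace(10, 1e4, 10):
            r = resid([lam0, np.log(hw), np.log(ns)])
            rss = float(r @ r)
            if best is None or rss < best[0]:
                best = (rss, hw, ns)
    _, hw0, ns0 = best

    sol = least_squares(
        resid,
        x0=[lam0, np.log(hw0), np.log(ns0)],
        bounds=(
            [lambda_bounds[0], np.log(omega_bounds[0]), np.log(2.0)],
            [lambda_bounds[1], np.log(omega_bounds[1]), np.log(1e7)],
        ),
        xtol=1e-12,
        ftol=1e-12,
    )
    lam, hw, ns = sol.x[0], float(np.exp(sol.x[1])), float(np.exp(sol.x[2]))
    m = model_logG(lam, hw, ns)
    scale = float(np.exp(np.mean(logG - m)))

    T_C = crossover_temperature(hw)
    # field response: relative span of G across E at the lowest temperature
    lowT_G = surface.G[-1][np.isfinite(surface.G[-1])]
    flat_field = lowT_G.size < 2 or (np.ptp(np.log(lowT_G)) < 0.05)
    return {
        "lambda_eV": float(lam),
        "omega_eff_meV": hw,
        "N_S": ns,
        "scale": scale,
        "residual_norm": float(np.sqrt(np.mean(sol.fun**2))),
        "omega_non_identifiable": bool(Tg.min() > T_C),
        "N_S_non_identifiable": bool(flat_field),
    }
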