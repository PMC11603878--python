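"""Fiber-geometry conversions.

Turns measured conductances into per-fiber conductivities and back:
sigma = G0 L / (N_F A_F); the transfer-length method sigma = 4/(N_F pi d_F^2 b)
from the slope b of resistance versus probed length; the hopping-frequency
constraint Gamma = sigma 4 k_B T A_F / (e^2 N_C delta); and the Joule-heating
bound dT_f = G V^2 h / (2 k w L).

Default constants describe the extracted cable-bacterium fiber skeleton:
N_F = 68 parallel fibers of conductive-core diameter d_F = 26 nm, up to
N_C = 30 conduction channels per fiber with an assumed cofactor spacing of
0.78 nm, and a flat segment h = 300 nm tall, w = 4 um wide with protein
thermal conductivity 0.3 W/mK.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import yaml

from .constants import CONST

__all__ = [
    "SegmentGeometry",
    "fiber_conductivity",
    "transfer_length_fit",
    "hopping_frequency",
    "joule_heating",
    "load_geometry",
    "save_geometry",
]


@dataclass(frozen=True)
class SegmentGeometry:
    """Geometry of one measured fiber-skeleton segment.

    L : segment length (um).
    N_F : number of parallel fibers in the skeleton.
    d_F : conductive-core diameter of a single fiber (nm).
    N_C : parallel conduction channels per fiber.
    delta_site : assumed cofactor center-to-center spacing (nm).
    h, w : skeleton height (nm) and width (um) for the heating estimate.
    k_protein : protein thermal conductivity (W/mK).

    The fiber cross-section A_F = pi d_F^2 / 4 is always derived from d_F.
    """

    L: float = 4.0
    N_F: int = 68
    d_F: float = 26.0
    N_C: int = 30
    delta_site: float = 0.78
    h: float = 300.0
    w: float = 4.0
    k_protein: float = 0.3

    def __post_init__(self) -> None:
        for name in ("L", "d_F", "delta_site", "h", "w", "k_protein"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.N_F < 1 or self.N_C < 1:
            raise ValueError("N_F and N_C must be >= 1")

    @property
    def A_F(self) -> float:
        """Single-fiber cross-sectional area in m^2."""
        d = self.d_F * 1e-9
        return math.pi * d**2 / 4.0


def fiber_conductivity(G0: float, geom: SegmentGeometry) -> float:
    """Per-fiber conductivity sigma = G0 L / (N_F A_F), in S/cm.

    G0 is the measured (zero-bias) segment conductance in S and L the probed
    length from the geometry (um).
    """
    if G0 < 0:
        raise ValueError(f"conductance must be >= 0, got {G0}")
    sigma_SI = G0 * (geom.L * 1e-6) / (geom.N_F * geom.A_F)  # S/m
    return sigma_SI / 100.0


def conductance_from_conductivity(sigma: float, geom: SegmentGeometry) -> float:
    """Inverse of `fiber_conductivity`: G0 (S) from sigma in S/cm."""
    return sigma * 100.0 * geom.N_F * geom.A_F / (geom.L * 1e-6)


def transfer_length_fit(L_um, R_ohm, geom: Optional[SegmentGeometry] = None):
    """Transfer-length method: conductivity from resistance versus length.

    Fits R = a + b L by OLS over >= 3 points with strictly increasing L and
    converts the slope with sigma = 4 / (N_F pi d_F^2 b).  Contact offsets at
    intervening electrodes shift the intercept a, not the slope.

    Returns a dict with slope_ohm_per_m, intercept_ohm, sigma_S_per_cm, r2.
    """
    geom = geom or SegmentGeometry()
    L_um = np.asarray(L_um, dtype=float)
    R_ohm = np.asarray(R_ohm, dtype=float)
    if L_um.size < 3:
        raise ValueError("need at least 3 (L, R) points")
    if np.any(np.diff(L_um) <= 0):
        raise ValueError("L values must be strictly increasing")
    L_m = L_um * 1e-6
    b, a = np.polyfit(L_m, R_ohm, 1)
    if b <= 0:
        raise ValueError("nonpositive fitted slope: invalid R(L) data")
    resid = R_ohm - (a + b * L_m)
    ss_tot = np.sum((R_ohm - R_ohm.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    d_m = geom.d_F * 1e-9
    sigma_SI = 4.0 / (geom.N_F * math.pi * d_m**2 * b)  # S/m
    return {
        "slope_ohm_per_m": float(b),
        "intercept_ohm": float(a),
        "sigma_S_per_cm": sigma_SI / 100.0,
        "r2": r2,
    }


def hopping_frequency(sigma: float, T: float, geom: SegmentGeometry) -> float:
    """Single-hop frequency Gamma = sigma 4 k_B T A_F / (e^2 N_C delta), s^-1.

    The transition frequency each channel's sites must sustain for the
    network to deliver conductivity `sigma` (S/cm) at temperature T, given
    N_C channels per fiber and site spacing delta.  Exactly linear in sigma,
    T and A_F, inversely linear in N_C and delta.
    """
    if sigma <= 0 or T <= 0:
        raise ValueError("sigma and T must be > 0")
    sigma_SI = sigma * 100.0  # S/m
    delta_m = geom.delta_site * 1e-9
    return (
        sigma_SI * 4.0 * CONST.k_B_J * T * geom.A_F / (CONST.e**2 * geom.N_C * delta_m)
    )


def joule_heating(
    G: float, V: float, geom: SegmentGeometry, L: Optional[float] = None
) -> float:
    """Filament self-heating bound dT_f = P h / (2 k w L) in K, P = G V^2.

    A flat-rectangular-segment estimate; substrate heating is neglected
    because the substrate conducts heat far better than the protein.
    """
    if G < 0:
        raise ValueError("conductance must be >= 0")
    L_m = (geom.L if L is None else L) * 1e-6
    if L_m <= 0:
        raise ValueError("L must be > 0")
    P = G * V**2
    return P * (geom.h * 1e-9) / (2.0 * geom.k_protein * (geom.w * 1e-6) * L_m)


def save_geometry(geom: SegmentGeometry, path) -> None:
    """Write geometry constants to a YAML (or JSON by extension) config."""
    d = asdict(geom)
    text = (
        json.dumps(d, indent=2)
        if str(path).endswith(".json")
        else yaml.safe_dump(d, sort_keys=False)
    )
    with open(path, "w") as fh:
        fh.write(text)


def load_geometry(path, **overrides) -> SegmentGeometry:
    """Load geometry from YAML/JSON, applying per-segment overrides."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d.update(overrides)
    return SegmentGeometry(**d)
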