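"""Reduction of raw I(V) sweeps to conductance observables.

Implements the measurement-side arithmetic: nondifferential conductance
G = [I(+V) - I(-V)]/(2V), the zero-bias differential conductance from a
linear regression in a low-bias window, the indicative electric field
E = V/L, two-/four-probe contact-resistance arithmetic R_C = R_2P - R_4P,
sweep symmetry/hysteresis diagnostics, and detection-floor masking.

Traces are immutable: every reduction returns new objects and never mutates
the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = [
    "IVTrace",
    "IVDataset",
    "nondiff_conductance",
    "zero_bias_conductance",
    "electric_field",
    "contact_resistance",
    "symmetry_and_hysteresis_check",
    "apply_detection_floor",
    "read_ivt_csv",
    "write_ivt_csv",
]

_PROBE_MODES = ("two_probe", "four_probe")


@dataclass(frozen=True)
class IVTrace:
    """One symmetric I(V) sweep at a fixed temperature.

    temperature : K.
    probe_mode : "two_probe" or "four_probe".
    bias : ordered bias voltages (V).
    current : measured currents (A), same length as bias.
    segment_length : probed segment length L (um).
    detection_floor : instrument current floor (A); points below it are
        masked, not deleted.
    mask : boolean array, True where the point is below detection.
    """

    temperature: float
    probe_mode: str
    bias: np.ndarray
    current: np.ndarray
    segment_length: float = 1.0
    detection_floor: float = 0.0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bias", np.asarray(self.bias, dtype=float))
        object.__setattr__(self, "current", np.asarray(self.current, dtype=float))
        if self.probe_mode not in _PROBE_MODES:
            raise ValueError(f"probe_mode must be one of {_PROBE_MODES}")
        if self.bias.shape != self.current.shape:
            raise ValueError("bias and current must have the same shape")
        if not (np.all(np.isfinite(self.bias)) and np.all(np.isfinite(self.current))):
            raise ValueError("bias and current must be finite")
        if self.mask is None:
            object.__setattr__(self, "mask", np.zeros(self.bias.shape, dtype=bool))
        else:
            object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def fully_masked(self) -> bool:
        return bool(self.mask.all())


@dataclass
class IVDataset:
    """A collection of IVTraces for one segment, one per temperature."""

    segment_id: str
    traces: List[IVTrace]
    geometry: object = None

    def __post_init__(self) -> None:
        temps = [t.temperature for t in self.traces]
        if len(set(temps)) != len(temps):
            raise ValueError("one trace per temperature expected")
        modes = {t.probe_mode for t in self.traces}
        if len(modes) > 1:
            raise ValueError("probe_mode must be consistent within a dataset")
        # cooldown order: descending temperature
        self.traces = sorted(self.traces, key=lambda t: -t.temperature)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t.temperature for t in self.traces])

    def trace_at(self, T: float) -> IVTrace:
        for t in self.traces:
            if np.isclose(t.temperature, T):
                return t
        raise KeyError(f"no trace at T = {T} K")


def _current_at(trace: IVTrace, V: float, interpolate: bool) -> float:
    ok = ~trace.mask
    bias, cur = trace.bias[ok], trace.current[ok]
    hit = np.isclose(bias, V, rtol=0, atol=1e-12 + 1e-9 * abs(V))
    if hit.any():
        return float(cur[hit].mean())  # mean over forward/backward repeats
    if not interpolate:
        raise ValueError(
            f"no sample at V = {V}; pass interpolate=True to allow "
            "linear interpolation on the sweep"
        )
    order = np.argsort(bias)
    return float(np.interp(V, bias[order], cur[order]))


def nondiff_conductance(trace: IVTrace, V: float, interpolate: bool = False) -> float:
    """Nondifferential conductance G = [I(+V) - I(-V)] / (2V) in S.

    Uses the symmetric +/-V pair of the sweep; if one partner is missing,
    linear interpolation may be enabled explicitly.  V must be nonzero.
    """
    if V == 0:
        raise ValueError("nondifferential conductance is undefined at V = 0")
    ip = _current_at(trace, abs(V), interpolate)
    im = _current_at(trace, -abs(V), interpolate)
    return (ip - im) / (2.0 * abs(V))


def zero_bias_conductance(
    trace: IVTrace, window_fraction: float = 0.10, min_points: int = 4
) -> float:
    """Zero-bias differential conductance G0 (S) by OLS in a low-bias window.

    The slope of I on V over |V| <= window_fraction * max|V| (at least
    `min_points` unmasked points).  Equals the nondifferential value for
    linear traces.
    """
    ok = ~trace.mask
    bias, cur = trace.bias[ok], trace.current[ok]
    if bias.size == 0:
        raise ValueError("trace is fully masked")
    if bias.size < min_points:
        raise ValueError(
            f"only {bias.size} unmasked points; need >= {min_points}"
        )
    vmax = np.abs(bias).max()
    sel = np.abs(bias) <= window_fraction * vmax + 1e-15
    if sel.sum() < min_points:
        # widen to the min_points samples closest to zero bias
        sel = np.zeros_like(sel)
        sel[np.argsort(np.abs(bias), kind="stable")[:min_points]] = True
    slope, _ = np.polyfit(bias[sel], cur[sel], 1)
    return float(slope)


def electric_field(V: float, L: float, probe_mode: str = "four_probe"):
    """Indicative electric field E = V/L in V/um for L in um.

    Returns (E, indicative) where the flag is True for two-probe data:
    part of V then drops over the contacts, so E is an upper bound on the
    intrinsic field.
    """
    if L <= 0:
        raise ValueError(f"segment length must be > 0, got {L}")
    if probe_mode not in _PROBE_MODES:
        raise ValueError(f"probe_mode must be one of {_PROBE_MODES}")
    return V / L, probe_mode == "two_probe"


def contact_resistance(R_2P: float, R_4P: float):
    """Contact resistance R_C = R_2P - R_4P and its fraction of the total.

    Returns (R_C, R_C / R_2P).  Raises if R_2P < R_4P, which signals an
    inconsistent measurement pair.
    """
    if R_4P <= 0:
        raise ValueError(f"R_4P must be > 0, got {R_4P}")
    if R_2P < R_4P:
        raise ValueError(
            f"R_2P ({R_2P}) < R_4P ({R_4P}): inconsistent measurement pair"
        )
    rc = R_2P - R_4P
    return rc, rc / R_2P


def symmetry_and_hysteresis_check(trace: IVTrace) -> Dict[str, float]:
    """Sweep diagnostics: bias asymmetry and forward/backward hysteresis.

    asymmetry = max|I(+V) + I(-V)| / max|I| over the +/- pairs present
    (0 for a perfectly odd curve); hysteresis = max spread between repeated
    samples at the same bias, normalised the same way.  Both near zero for
    valid quasi-static data.
    """
    ok = ~trace.mask
    bias, cur = trace.bias[ok], trace.current[ok]
    imax = np.abs(cur).max() if cur.size else 0.0
    if imax == 0:
        return {"asymmetry": 0.0, "hysteresis": 0.0}
    # group repeated samples per bias value
    order = np.argsort(bias)
    bias_s, cur_s = bias[order], cur[order]
    uniq, start = np.unique(np.round(bias_s, 12), return_index=True)
    means, spreads = {}, []
    for k, v in enumerate(uniq):
        seg = cur_s[start[k] : start[k + 1] if k + 1 < uniq.size else None]
        means[v] = seg.mean()
        if seg.size > 1:
            spreads.append(np.ptp(seg))
    asym = 0.0
    for v, m in means.items():
        if v > 0 and -v in means:
            asym = max(asym, abs(m + means[-v]))
    return {
        "asymmetry": asym / imax,
        "hysteresis": (max(spreads) if spreads else 0.0) / imax,
    }


def apply_detection_floor(trace: IVTrace, floor: Optional[float] = None) -> IVTrace:
    """Mask points with |I| below the detection floor; never deletes them.

    Uses the trace's own floor unless `floor` overrides it.  Conductance
    operations skip masked points.
    """
    f = trace.detection_floor if floor is None else floor
    if f < 0:
        raise ValueError(f"detection floor must be >= 0, got {f}")
    new_mask = trace.mask | (np.abs(trace.current) < f)
    return replace(trace, mask=new_mask, detection_floor=f)


# ---------------------------------------------------------------------------
# Delimited-text I/O (also accepts externally supplied exports in the same
# layout: segment_id, probe_mode, temperature_K, bias_V, current_A[, masked])

_COLUMNS = ["segment_id", "probe_mode", "temperature_K", "bias_V", "current_A"]


def write_ivt_csv(dataset: IVDataset, path, sep: str = ",") -> None:
    """Write a dataset as a tidy delimited table."""
    rows = []
    for t in dataset.traces:
        for v, i, m in zip(t.bias, t.current, t.mask):
            rows.append(
                {
                    "segment_id": dataset.segment_id,
                    "probe_mode": t.probe_mode,
                    "temperature_K": t.temperature,
                    "bias_V": v,
                    "current_A": i,
                    "masked": bool(m),
                    "segment_length_um": t.segment_length,
                    "detection_floor_A": t.detection_floor,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_ivt_csv(path, sep: str = ",") -> List[IVDataset]:
    """Read one or more segments from a tidy delimited I-V-T table."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"I-V-T table is missing required columns: {missing}")
    datasets = []
    for seg, sdf in df.groupby("segment_id", sort=False):
        traces = []
        for T, tdf in sdf.groupby("temperature_K", sort=False):
            traces.append(
                IVTrace(
                    temperature=float(T),
                    probe_mode=str(tdf["probe_mode"].iloc[0]),
                    bias=tdf["bias_V"].to_numpy(),
                    current=tdf["current_A"].to_numpy(),
                    segment_length=float(tdf["segment_length_um"].iloc[0])
                    if "segment_length_um" in tdf
                    else 1.0,
                    detection_floor=float(tdf["detection_floor_A"].iloc[0])
                    if "detection_floor_A" in tdf
                    else 0.0,
                    mask=tdf["masked"].to_numpy(dtype=bool)
                    if "masked" in tdf
                    else None,
                )
            )
        datasets.append(IVDataset(segment_id=str(seg), traces=traces))
    return datasets
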