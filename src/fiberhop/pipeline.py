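"""End-to-end analysis pipeline.

Runs the full reduction-and-fitting chain on one or more segments:

    acquire (simulate or load) -> reduce sweeps to G observables
    -> high-T fits (lambda, U_A) -> crossover scan -> low-T power laws
    (alpha, beta) -> universal-scaling fit and collapse -> geometry
    conversions (sigma, R_C fraction) -> structured report.

Intermediate artifacts are plain delimited text and JSON, every fit's
window, point count and convergence status is logged, and a config plus
seed fully determine all outputs (re-runs are hash-identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .fiber_geometry import SegmentGeometry, fiber_conductivity
from .iv_reduction import (
    IVDataset,
    nondiff_conductance,
    read_ivt_csv,
    write_ivt_csv,
    zero_bias_conductance,
)
from .synthetic_data import fixture_fig3c, fixture_fig3d, generate_ivt
from .transport_fits import (
    detect_crossover,
    fit_arrhenius,
    fit_marcus_lambda,
    fit_power_law_field,
    fit_power_law_temperature,
    fit_universal_scaling,
    scaling_collapse,
)

log = logging.getLogger("fiberhop")

_FIXTURES = {"fig3c": fixture_fig3c, "fig3d": fixture_fig3d}


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run.

    input_csv : path to a tidy I-V-T table, or None to simulate.
    fixture : name of a built-in synthetic spec ("fig3c" or "fig3d") used
        when input_csv is None.
    noise : multiplicative noise scale for the simulated fixture.
    T_min_arrhenius : lower edge (K) of the high-temperature fit window.
    power_law_T_range : window (K) for the G ~ T^alpha fit.
    crossover_threshold : relative deviation defining the crossover (0.20).
    scaling_T_max : include T below this in the universal-scaling fit;
        None means "below the detected crossover".
    out_dir : where artifacts are written (None: nothing persisted).
    seed : RNG seed for simulation.
    """

    input_csv: Optional[str] = None
    fixture: str = "fig3d"
    noise: float = 0.0
    geometry_overrides: Dict[str, float] = field(default_factory=dict)
    T_min_arrhenius: float = 100.0
    power_law_T_range: Tuple[float, float] = (20.0, 100.0)
    crossover_threshold: float = 0.20
    scaling_T_max: Optional[float] = None
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.crossover_threshold < 1.0:
            raise ValueError("crossover_threshold must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "power_law_T_range" in data:
            data["power_law_T_range"] = tuple(data["power_law_T_range"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class FitReport:
    """Per-segment parameter table plus run metadata."""

    segments: Dict[str, dict]
    config_hash: str
    seed: int
    version: str = __version__
    complete: bool = True

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "segments": self.segments,
                "metadata": {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "version": self.version,
                    "complete": self.complete,
                },
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def acquire(config: AnalysisConfig) -> List[IVDataset]:
    """Load the input table or synthesise the configured fixture."""
    if config.input_csv is not None:
        datasets = read_ivt_csv(config.input_csv)
        if not datasets or all(len(d.traces) == 0 for d in datasets):
            raise ValueError(f"no traces found in {config.input_csv}")
        return datasets
    try:
        make = _FIXTURES[config.fixture]
    except KeyError:
        raise ValueError(
            f"unknown fixture {config.fixture!r}; available: {sorted(_FIXTURES)}"
        ) from None
    spec = make(seed=config.seed, noise=config.noise)
    return [generate_ivt(spec)]


def reduce_dataset(dataset: IVDataset, n_fields: int = 4):
    """Reduce sweeps to G(T) curves at a few fixed biases plus G0(T).

    Returns a dict with arrays T, G0, and per-bias nondifferential G(T)
    columns at fractions of the sweep maximum, and the per-point (T, V, I)
    arrays used by the scaling fit.
    """
    usable = [t for t in dataset.traces if not t.fully_masked]
    if not usable:
        raise ValueError(f"segment {dataset.segment_id}: all traces masked")
    vmax = max(np.abs(t.bias).max() for t in usable)
    fracs = np.linspace(1.0 / n_fields, 1.0, n_fields)
    out = {"T": [], "G0": [], "bias_values": vmax * fracs, "G_at_bias": []}
    Tp, Vp, Ip = [], [], []
    for t in usable:
        try:
            g0 = zero_bias_conductance(t)
        except ValueError:
            g0 = np.nan
        row = []
        for v in vmax * fracs:
            try:
                row.append(nondiff_conductance(t, v, interpolate=True))
            except ValueError:
                row.append(np.nan)
        out["T"].append(t.temperature)
        out["G0"].append(g0)
        out["G_at_bias"].append(row)
        ok = ~t.mask
        Tp += [t.temperature] * int(ok.sum())
        Vp += list(t.bias[ok])
        Ip += list(t.current[ok])
    out["T"] = np.array(out["T"])
    out["G0"] = np.array(out["G0"])
    out["G_at_bias"] = np.array(out["G_at_bias"])
    out["points"] = (np.array(Tp), np.array(Vp), np.array(Ip))
    out["segment_length_um"] = usable[0].segment_length
    return out


def run_pipeline(config: AnalysisConfig) -> FitReport:
    """Execute all stages; per-segment failures are isolated and reported."""
    datasets = acquire(config)
    geom_kwargs = dict(config.geometry_overrides)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    segments: Dict[str, dict] = {}
    complete = True
    for ds in datasets:
        try:
            segments[ds.segment_id] = _analyse_segment(ds, config, geom_kwargs, out_dir)
        except Exception as err:  # stage isolation
            log.error("segment %s failed: %s", ds.segment_id, err)
            segments[ds.segment_id] = {"error": str(err)}
            complete = False
        if out_dir:
            write_ivt_csv(ds, out_dir / f"{ds.segment_id}_ivt.csv")

    report = FitReport(
        segments=segments,
        config_hash=config.config_hash(),
        seed=config.seed,
        complete=complete,
    )
    if out_dir:
        report.to_json(out_dir / "fit_report.json")
    return report


def _analyse_segment(ds: IVDataset, config, geom_kwargs, out_dir) -> dict:
    red = reduce_dataset(ds)
    T, G0 = red["T"], red["G0"]
    L = red["segment_length_um"]
    result: dict = {"n_temperatures": int(T.size), "segment_length_um": L}

    # high-temperature fits on the low-bias conductance
    lam_fit = fit_marcus_lambda(T, G0, T_min=config.T_min_arrhenius)
    arr_fit = fit_arrhenius(T, G0, T_min=config.T_min_arrhenius)
    result["lambda_meV"] = lam_fit.lambda_meV
    result["U_A_meV"] = arr_fit.U_A_meV
    result["fit_windows"] = {
        "marcus_T_range_K": lam_fit.T_range,
        "arrhenius_T_range_K": arr_fit.T_range,
        "arrhenius_r2": arr_fit.r_squared,
    }
    log.info(
        "%s: lambda = %.0f meV, U_A = %.1f meV on T in %s",
        ds.segment_id, lam_fit.lambda_meV, arr_fit.U_A_meV, arr_fit.T_range,
    )

    # crossover scan (absence is a valid outcome)
    cx = detect_crossover(T, G0, arr_fit, threshold=config.crossover_threshold)
    result["T_C_K"] = cx.T_C

    # low-temperature power laws
    try:
        alpha = fit_power_law_temperature(T, G0, T_range=config.power_law_T_range)
        result["alpha"] = alpha.exponent
    except ValueError as err:
        result["alpha"] = None
        log.info("%s: alpha fit skipped (%s)", ds.segment_id, err)

    coldest = min((t for t in ds.traces if not t.fully_masked), key=lambda t: t.temperature)
    try:
        ok = ~coldest.mask & (coldest.bias > 0)
        E = coldest.bias[ok] / L
        Gv = coldest.current[ok] / coldest.bias[ok]
        beta_pl = fit_power_law_field(E[E >= np.median(E)], Gv[E >= np.median(E)])
        result["beta_power_law"] = beta_pl.exponent
    except ValueError as err:
        result["beta_power_law"] = None
        log.info("%s: beta fit skipped (%s)", ds.segment_id, err)

    # universal-scaling fit on low-temperature sweeps
    # default window: below the detected crossover, widened to the coldest
    # few temperatures when the crossover sits too low to leave >= 3 sweeps
    T_max = config.scaling_T_max
    if T_max is None:
        T_max = cx.T_C if cx.T_C is not None else float(np.median(T))
        T_sorted = np.sort(T)
        if (T_sorted <= T_max).sum() < 3 and T_sorted.size >= 3:
            T_max = float(T_sorted[min(3, T_sorted.size - 1)])
    Tp, Vp, Ip = red["points"]
    try:
        sc = fit_universal_scaling(Tp, Vp, Ip, T_max=T_max)
        u, ynorm, spread = scaling_collapse(
            Tp[Tp <= T_max], Vp[Tp <= T_max], Ip[Tp <= T_max], sc
        )
        result.update(
            {
                "beta_scaling": sc.beta,
                "N_S": sc.N_S,
                "B0": sc.B0,
                "collapse_spread_log10": spread,
                "scaling_T_max_K": T_max,
            }
        )
        if out_dir is not None:
            np.savetxt(
                out_dir / f"{ds.segment_id}_collapse.csv",
                np.column_stack([u, ynorm]),
                delimiter=",",
                header="u,I_over_T_1plusbeta",
                comments="",
            )
    except ValueError as err:
        result.update({"beta_scaling": None, "N_S": None, "B0": None})
        log.info("%s: scaling fit skipped (%s)", ds.segment_id, err)

    # geometry conversions at the warmest temperature
    geom = ds.geometry if isinstance(ds.geometry, SegmentGeometry) else None
    if geom is None:
        geom = SegmentGeometry(L=L, **geom_kwargs)
    g0_room = G0[np.argmax(T)]
    if np.isfinite(g0_room) and g0_room > 0:
        result["sigma0_S_per_cm"] = fiber_conductivity(float(g0_room), geom)
    result["probe_mode"] = ds.traces[0].probe_mode
    return result
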