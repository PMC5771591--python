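"""Reproducible experiment drivers for the three simulation sets.

* :func:`run_single_cell_stretch` — steady-stretch single-cell runs
  (52 pA/pF x 1 ms stimulus) over a list of stretch ratios;
* :func:`run_ventricle_preload` — coupled ventricle beats over the preload
  series (0/10/15/20/25% of reference length), control and heart-failure
  arms, summarised as a stretch-ratio x min/max-APD table;
* :func:`run_hf_comparison` — paired control/heart-failure 1-Hz single-cell
  traces and fixed-preload PV loops.

All protocols are fully deterministic (no random number generation
anywhere): identical specs produce bit-identical outputs.  Every CSV written
carries a provenance header (config hash, package version, time step,
parameter values).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _version
from .tnnp import (CellParams, StimulusSpec, apply_hf, equilibrate,
                   run_paced_cell)
from .sac import SacParams
from .ventricle import (VentricleGeometry, LoadingConditions,
                        simulate_ventricle, generate_pv_loop)
from .markers import detect_at, detect_rt
from .config import config_hash, default_hf_modifiers

__all__ = ["ExperimentSpec", "ConfigError", "run_single_cell_stretch",
           "run_ventricle_preload", "run_hf_comparison",
           "write_trace_csv", "save_state_h5", "repolarization_crossover"]

log = logging.getLogger("cardiomef")

PRELOAD_PERCENTS = (0, 10, 15, 20, 25)
SINGLE_CELL_LAMBDAS = (1.00, 1.10, 1.20, 1.25, 1.30)


class ConfigError(ValueError):
    """Invalid experiment specification."""


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: protocol id, stretch list, HF flag, numerics, outputs."""

    protocol: str = "single_cell_stretch"
    lambdas: tuple = SINGLE_CELL_LAMBDAS
    preload_percents: tuple = PRELOAD_PERCENTS
    hf: bool = False
    dt: float = 0.02                # ms
    duration: float = 1000.0        # ms, single-cell window
    tissue_duration: float = 560.0  # ms, ventricle window (control)
    hf_tissue_duration: float = 800.0  # ms, ventricle window (HF arm)
    equilibration: float = 5000.0   # ms
    record_stride: float = 0.1      # ms, single-cell sampling
    n_rings: int = 24
    nodes_per_ring: int = 24
    sac_enabled: bool = True
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.lambdas) == 0:
            raise ConfigError("lambda list must not be empty")
        if not (self.dt > 0):
            raise ConfigError(f"dt must be > 0, got {self.dt}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _provenance(spec: ExperimentSpec, extra: Optional[dict] = None) -> list:
    d = spec.as_dict()
    d.pop("out_dir", None)  # the hash covers the scientific configuration only
    lines = [
        f"# cardiomef v{_version}",
        f"# config_hash: {config_hash(d)}",
        f"# dt_ms: {spec.dt}",
        f"# protocol: {spec.protocol}",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def write_trace_csv(path, df: pd.DataFrame, header_lines: list) -> None:
    """CSV with '#'-prefixed provenance header lines before the table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def save_state_h5(path, arrays: dict, attrs: Optional[dict] = None) -> None:
    """Full state dump (HDF5): one dataset per array, scalar attrs on root."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        for name, arr in arrays.items():
            h5.create_dataset(name, data=np.asarray(arr))
        for k, v in (attrs or {}).items():
            h5.attrs[k] = v


def _cell_params(spec: ExperimentSpec) -> CellParams:
    p = CellParams()
    if spec.hf:
        p = apply_hf(p, default_hf_modifiers())
    return p


def _sac(spec: ExperimentSpec) -> Optional[SacParams]:
    return SacParams() if spec.sac_enabled else None


# ---------------------------------------------------------------------------
# protocol 1: single-cell steady stretch
# ---------------------------------------------------------------------------
def run_single_cell_stretch(spec: ExperimentSpec) -> dict:
    """AP traces at each steady stretch ratio in ``spec.lambdas``.

    Each configuration equilibrates quiescently at its λ (recruitment-gated
    SAC), then receives the 52 pA/pF x 1 ms stimulus at t = 0.  Returns
    ``{"traces": {λ: CellTrace}, "markers": DataFrame}``; all traces share
    one time grid.  Writes one trace CSV per λ plus a marker table when
    ``spec.out_dir`` is set.
    """
    if spec.protocol not in ("single_cell_stretch",):
        log.debug("running single-cell stretch under protocol id %s", spec.protocol)
    params = _cell_params(spec)
    sac = _sac(spec)
    stim = StimulusSpec(amplitude=52.0, onset=0.0, duration=1.0)
    traces = {}
    rows = []
    for lam in spec.lambdas:
        tr = run_paced_cell(params, stim, sac_config=sac, lam=lam,
                            duration=spec.duration, dt=spec.dt,
                            record_stride=spec.record_stride,
                            equilibration=spec.equilibration)
        traces[lam] = tr
        at = detect_at(tr.t, tr.vm)
        rt = detect_rt(tr.t, tr.vm, after=at) if at is not None else None
        failed = at is not None and rt is None
        if failed:
            log.warning("λ=%.2f: repolarization failure", lam)
        rows.append({
            "stretch_ratio": lam,
            "AT_ms": np.nan if at is None else at,
            "RT_ms": np.nan if rt is None else rt,
            "APD_ms": np.nan if (at is None or rt is None) else rt - at,
            "resting_Vm_mV": tr.vm[0],
            "peak_Vm_mV": tr.vm.max(),
            "repolarization_failed": failed,
        })
        log.info("single-cell λ=%.2f done (%.0f ms simulated)", lam, spec.duration)
    markers = pd.DataFrame(rows)
    if spec.out_dir:
        out = Path(spec.out_dir)
        for lam, tr in traces.items():
            df = pd.DataFrame({"time_ms": tr.t, "Vm_mV": tr.vm, "Cai_mM": tr.cai})
            write_trace_csv(out / f"ap_lambda_{lam:.2f}.csv", df,
                            _provenance(spec, {"lambda": lam, "hf": spec.hf}))
        write_trace_csv(out / "single_cell_markers.csv", markers, _provenance(spec))
    return {"traces": traces, "markers": markers}


# ---------------------------------------------------------------------------
# protocol 2: ventricle preload series
# ---------------------------------------------------------------------------
def _preload_to_lambda(percent: float) -> float:
    return 1.0 + percent / 100.0


def run_ventricle_preload(spec: ExperimentSpec, include_hf: bool = True) -> dict:
    """Coupled ventricle beats over the preload series; APD summary table.

    Returns ``{"table": DataFrame, "results": {(arm, percent): VentricleResult}}``
    where the table mirrors the published comparison: one row per stretch
    ratio with min/max APD for the control and heart-failure arms ("NA" on
    repolarization failure).  Writes ``preload_apd_table.csv`` and per-run
    marker maps when ``spec.out_dir`` is set.
    """
    geometry = VentricleGeometry(n_rings=spec.n_rings,
                                 nodes_per_ring=spec.nodes_per_ring)
    sac = _sac(spec)
    ctrl = CellParams()
    hfp = apply_hf(ctrl, default_hf_modifiers())
    arms = [("control", ctrl, spec.tissue_duration)]
    if include_hf:
        arms.append(("hf", hfp, spec.hf_tissue_duration))
    results = {}
    rows = {pct: {"stretch_ratio": _preload_to_lambda(pct)} for pct in spec.preload_percents}
    for arm, params, dur in arms:
        for pct in spec.preload_percents:
            lam_p = _preload_to_lambda(pct)
            res = simulate_ventricle(
                geometry, LoadingConditions(preload_stretch=lam_p),
                cell_params=params, sac_params=sac, duration=dur, dt=spec.dt,
                equilibration=spec.equilibration)
            results[(arm, pct)] = res
            m = res.markers
            if m.n_failed > 0:
                log.warning("%s preload %d%%: %d fibers failed to repolarize",
                            arm, pct, m.n_failed)
            rows[pct][f"min_apd_{arm}"] = m.min_apd
            rows[pct][f"max_apd_{arm}"] = m.max_apd
            log.info("ventricle %s preload %d%% done (%.0f ms simulated)",
                     arm, pct, dur)
    table = pd.DataFrame([rows[p] for p in spec.preload_percents])
    for col in ("min_apd_control", "min_apd_hf", "max_apd_control", "max_apd_hf"):
        if col not in table:
            table[col] = np.nan
    table = table[["stretch_ratio", "min_apd_control", "min_apd_hf",
                   "max_apd_control", "max_apd_hf"]]
    if spec.out_dir:
        out = Path(spec.out_dir)
        printable = table.copy()
        write_trace_csv(out / "preload_apd_table.csv",
                        printable.fillna("NA"), _provenance(spec))
        for (arm, pct), res in results.items():
            write_trace_csv(out / f"markers_{arm}_preload{pct:02d}.csv",
                            res.markers.to_dataframe(),
                            _provenance(spec, {"arm": arm, "preload_percent": pct}))
    return {"table": table, "results": results}


# ---------------------------------------------------------------------------
# protocol 3: control vs heart failure
# ---------------------------------------------------------------------------
def run_hf_comparison(spec: ExperimentSpec, prepace_beats: int = 10) -> dict:
    """Paired control/HF single-cell 1-Hz traces plus fixed-preload PV loops.

    The two arms share every parameter except the six heart-failure factors.
    Single cells are pre-paced ``prepace_beats`` beats at 1 Hz and the next
    beat is recorded (no stretch applied).  Returns traces, APDs and PV
    summaries; writes Fig-6-shaped CSVs when ``spec.out_dir`` is set.
    """
    ctrl = CellParams()
    hfp = apply_hf(ctrl, default_hf_modifiers())
    stim = StimulusSpec(amplitude=52.0, duration=1.0, period=1000.0)
    out = {}
    for arm, params in (("control", ctrl), ("hf", hfp)):
        rest = equilibrate(params, None, 1.0, duration=spec.equilibration,
                           dt=spec.dt)
        train = run_paced_cell(params, stim, sac_config=None, lam=1.0,
                               duration=(prepace_beats + 1) * 1000.0,
                               dt=spec.dt, initial_state=rest,
                               record_stride=spec.record_stride)
        k0 = int(round(prepace_beats * 1000.0 / spec.record_stride))
        t = train.t[k0:] - train.t[k0]
        vm = train.vm[k0:]
        at = detect_at(t, vm)
        rt = detect_rt(t, vm, after=at) if at is not None else None
        apd = None if (at is None or rt is None) else rt - at
        geometry = VentricleGeometry(n_rings=spec.n_rings,
                                     nodes_per_ring=spec.nodes_per_ring)
        res = simulate_ventricle(geometry, LoadingConditions(),
                                 cell_params=params, sac_params=_sac(spec),
                                 duration=spec.tissue_duration, dt=spec.dt,
                                 equilibration=spec.equilibration)
        pv = generate_pv_loop(res.pv)
        out[arm] = {"t": t, "vm": vm, "cai": train.cai[k0:], "apd": apd,
                    "pv_summary": pv, "pv": res.pv}
        log.info("hf-comparison arm %s: APD=%.1f ms, SV=%.1f mL", arm,
                 -1 if apd is None else apd, pv.stroke_volume)
    if spec.out_dir:
        outdir = Path(spec.out_dir)
        for arm in ("control", "hf"):
            d = out[arm]
            write_trace_csv(outdir / f"ap_1hz_{arm}.csv",
                            pd.DataFrame({"time_ms": d["t"], "Vm_mV": d["vm"],
                                          "Cai_mM": d["cai"]}),
                            _provenance(spec, {"arm": arm}))
            write_trace_csv(outdir / f"pv_loop_{arm}.csv",
                            pd.DataFrame({"time_ms": d["pv"].time,
                                          "volume_mL": d["pv"].volume,
                                          "pressure_mmHg": d["pv"].pressure}),
                            _provenance(spec, {"arm": arm}))
    return out


def repolarization_crossover(t, vm_ref, vm_stretched):
    """Voltage at which two AP traces intersect during repolarization.

    Finds the first sign change of (vm_ref - vm_stretched) after both traces
    have passed their peaks, linearly interpolated; returns ``(time_ms,
    voltage_mV)`` or ``None`` when the traces never cross.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(vm_ref, dtype=float)
    b = np.asarray(vm_stretched, dtype=float)
    start = max(int(a.argmax()), int(b.argmax()))
    d = a[start:] - b[start:]
    sign = np.sign(d)
    idx = np.where(np.diff(sign) != 0)[0]
    idx = idx[np.abs(d[idx]) > 0] if idx.size else idx
    if idx.size == 0:
        return None
    k = start + int(idx[0])
    w = d[idx[0]] / (d[idx[0]] - d[idx[0] + 1])
    tc = t[k] + w * (t[k + 1] - t[k])
    vc = a[k] + w * (a[k + 1] - a[k])
    return float(tc), float(vc)
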