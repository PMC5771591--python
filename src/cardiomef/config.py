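"""Human-readable (YAML) configuration for all model components.

A configuration file has up to seven sections, each optional (missing keys
fall back to the built-in defaults)::

    cell:      {g_na, g_k1, g_to, g_kr, g_ks, g_pk, g_cal, k_naca, p_nak,
                g_pca, g_bna, g_bca, cm}
    hf:        {enabled, f_ito, f_iks, f_ik1, f_ina, f_ical, f_inaca}
    sac:       {enabled, g_sac, v_rev, k, alpha, half_sl0}
    stimulus:  {amplitude, onset, duration, period}          # single cell
    myofilament: {tt, y1, z1, y2, z2, y3, z3, y4, yd, b, hc, l_opt, w_ov,
                a_force}
    geometry:  {n_rings, nodes_per_ring, base_radius, long_axis,
                theta_min_deg}
    loading:   {preload_stretch, filling_pressure, windkessel_r,
                windkessel_c, arterial_pressure0, valve_resistance,
                fill_resistance, force_to_pressure, passive_kp, passive_bp,
                force_scale}
    numerics:  {dt, dt_mech, duration, record_stride, equilibration,
                coupling, stim_amplitude, stim_duration}

``sac.enabled: false`` is equivalent to G_SAC = 0.  The packaged
``configs/hf_default.yaml`` carries the default heart-failure factors (a
documented calibration artifact; see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from typing import Optional

import yaml

from .tnnp import CellParams, HfModifiers, StimulusSpec
from .sac import SacParams
from .myofilament import NlParams
from .ventricle import VentricleGeometry, LoadingConditions

__all__ = [
    "load_config", "save_config", "config_hash", "default_hf_modifiers",
    "build_cell_params", "build_sac_params", "build_stimulus",
    "build_geometry", "build_loading", "build_nl_params", "NUMERICS_DEFAULTS",
]

NUMERICS_DEFAULTS = {
    "dt": 0.02,             # ms, electrophysiology step
    "dt_mech": 1.0,         # ms, mechanics step
    "duration": 560.0,      # ms, ventricle beat window
    "record_stride": 0.2,   # ms, Vm sampling
    "equilibration": 5000.0,  # ms, quiescent pre-run relaxation
    "coupling": 4.0e6,      # µm²/ms, monodomain diffusion coefficient
    "stim_amplitude": 15.85,  # pA/pF, tissue (apex) stimulus
    "stim_duration": 6.0,   # ms, tissue stimulus length
}


def _filtered(cls, d: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names - {"enabled"}
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return {k: v for k, v in d.items() if k in names}


def load_config(path) -> dict:
    """Read a YAML config file into a plain dict (empty file -> {})."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg)}")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration (provenance headers)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def build_cell_params(cfg: dict) -> CellParams:
    return CellParams(**_filtered(CellParams, cfg.get("cell", {})))


def default_hf_modifiers() -> HfModifiers:
    """The packaged heart-failure factor set (configs/hf_default.yaml)."""
    text = resources.files("cardiomef").joinpath("configs/hf_default.yaml").read_text()
    d = yaml.safe_load(text)["hf"]
    d.pop("enabled", None)
    return HfModifiers(**d)


def build_hf_modifiers(cfg: dict) -> Optional[HfModifiers]:
    hf = cfg.get("hf")
    if hf is None:
        return None
    if not hf.get("enabled", True):
        return None
    d = _filtered(HfModifiers, hf)
    if d:
        return HfModifiers(**d)
    return default_hf_modifiers()


def build_sac_params(cfg: dict) -> Optional[SacParams]:
    sac = cfg.get("sac", {})
    if not sac.get("enabled", True):
        return None
    return SacParams(**_filtered(SacParams, sac))


def build_stimulus(cfg: dict) -> StimulusSpec:
    return StimulusSpec(**_filtered(StimulusSpec, cfg.get("stimulus", {})))


def build_nl_params(cfg: dict) -> NlParams:
    return NlParams(**_filtered(NlParams, cfg.get("myofilament", {})))


def build_geometry(cfg: dict) -> VentricleGeometry:
    return VentricleGeometry(**_filtered(VentricleGeometry, cfg.get("geometry", {})))


def build_loading(cfg: dict, preload_stretch: Optional[float] = None) -> LoadingConditions:
    d = _filtered(LoadingConditions, cfg.get("loading", {}))
    if preload_stretch is not None:
        d["preload_stretch"] = preload_stretch
    return LoadingConditions(**d)


def numerics(cfg: dict) -> dict:
    out = dict(NUMERICS_DEFAULTS)
    extra = cfg.get("numerics", {})
    unknown = set(extra) - set(out)
    if unknown:
        raise KeyError(f"unknown numerics keys: {sorted(unknown)}")
    out.update(extra)
    return out
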