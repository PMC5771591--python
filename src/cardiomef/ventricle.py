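"""Fiber-based 3D ventricle: geometry, propagation, mechanics, MEF loop.

The ventricle wall is a single layer of circular myocardial fiber rings
stacked from apex to base on a truncated prolate spheroid of revolution.
Each node on a ring carries a full myocyte state and a sarcomere state.
Electrical excitation propagates through an isotropic monodomain
(reaction–diffusion) equation discretized with explicit finite differences on
the (ring, node) surface grid: periodic circumferentially, no-flux at the
apex and base openings.

Mechanics close the mechano-electric feedback loop.  Each ring is a loop of
identical half-sarcomeres in series, so its circumference C_i fixes the local
half-sarcomere length ``HalfSL_i = C_i / N_i`` and hence the stretch ratio
``λ_i = HalfSL_i / HalfSL0``; N_i is the number of half-sarcomeres the
unstressed ring holds.  Cavity volume follows from the ring radii by solid of
revolution; the cavity scales isotropically (λ = (V/V0)^(1/3), i.e. the long
axis shortens in proportion to the circumference, as the real ventricle
shortens longitudinally).  The cavity pressure is a lumped Laplace balance of
the area-weighted wall tension (active myofilament force + exponential
passive elasticity), and the beat runs through a four-phase state machine —
isovolumic contraction, ejection into a 2-element Windkessel afterload,
isovolumic relaxation, and filling at a constant filling pressure, truncated
at the prescribed preload stretch (fixed-preload protocol).

The updated λ field feeds the stretch-activated channel current and the
sarcomere length at the *next* electrophysiology step (one-mechanics-step
lagged explicit coupling); mechanics are updated every ``dt_mech`` (default
1 ms), far below the mechanical time scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from . import tnnp
from .tnnp import (CellParams, NSTATE, IV, ICAI,
                   NumericalInstabilityError, _step_one, _isac_node)
from .sac import SacParams
from .myofilament import (NlParams, NNL, _nl_step_one, _nl_force, HALF_SL0)
from .markers import MarkerTable, extract_markers

__all__ = [
    "VentricleGeometry", "LoadingConditions", "TissueState", "PvRecord",
    "VentricleResult", "StabilityError", "GeometryError", "diffusion_step",
    "update_geometry", "simulate_ventricle", "generate_pv_loop", "PvSummary",
]


class StabilityError(RuntimeError):
    """Explicit diffusion step violates the CFL bound."""


class GeometryError(ValueError):
    """Inconsistent or non-physical geometry input."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------
@dataclass
class VentricleGeometry:
    """Stack of circular fiber rings on a truncated prolate spheroid.

    Ring ``i`` sits at polar angle theta_i (measured from the apex pole),
    evenly spaced between ``theta_min_deg`` and 90 deg (the equator = base
    opening).  Unstressed ring radius r0_i = base_radius * sin(theta_i);
    axial position z0_i = -long_axis * cos(theta_i).  Default dimensions are
    sized to a human left ventricle (unstressed cavity volume ~117 mL).

    ``N`` is the number of half-sarcomeres along the outer boundary (the
    equatorial circumference L_V0) in the unstressed state, so λ = 1 at rest.
    """

    n_rings: int = 24
    nodes_per_ring: int = 24
    base_radius: float = 31000.0   # µm
    long_axis: float = 58000.0     # µm, apex-to-base semi-axis
    theta_min_deg: float = 15.0
    half_sl0: float = HALF_SL0     # µm
    apex_index: int = 0            # flat node id of the stimulus element

    def __post_init__(self) -> None:
        if self.n_rings < 1 or self.nodes_per_ring < 3:
            raise GeometryError("need n_rings >= 1 and nodes_per_ring >= 3")
        if self.base_radius <= 0 or self.long_axis <= 0:
            raise GeometryError("base_radius and long_axis must be > 0")
        th = np.linspace(math.radians(self.theta_min_deg), math.pi / 2.0,
                         self.n_rings)
        self.theta = th
        self.r0 = self.base_radius * np.sin(th)
        self.z0 = -self.long_axis * np.cos(th)
        # circumferential node spacing per ring (µm)
        self.dy = 2.0 * math.pi * self.r0 / self.nodes_per_ring
        # meridional arc between consecutive rings (µm; chord approximation)
        if self.n_rings > 1:
            self.dmer = np.sqrt(np.diff(self.r0) ** 2 + np.diff(self.z0) ** 2)
        else:
            self.dmer = np.zeros(0)

    @property
    def n_nodes(self) -> int:
        return self.n_rings * self.nodes_per_ring

    @property
    def l_v0(self) -> float:
        """Unstressed outer-boundary (equatorial) circumference L_V0 (µm)."""
        return 2.0 * math.pi * self.base_radius

    @property
    def n_half_sarcomeres(self) -> int:
        """N = L_V0 / HalfSL0, half-sarcomeres along the unstressed boundary."""
        return int(round(self.l_v0 / self.half_sl0))

    def ring_circumference(self, i: int) -> float:
        return 2.0 * math.pi * float(self.r0[i])

    def cavity_volume(self, lam: float = 1.0) -> float:
        """Cavity volume (mL) when every ring is stretched by ``lam``.

        Isotropic scaling: radii and axial positions scale together, so
        V(λ) = λ³ V(1).
        """
        if lam <= 0:
            raise GeometryError(f"lam must be > 0, got {lam}")
        r = self.r0
        z = self.z0
        # solid of revolution between rings + cone cap from the apex pole
        v = 0.0
        for i in range(self.n_rings - 1):
            v += math.pi * 0.5 * (r[i] ** 2 + r[i + 1] ** 2) * (z[i + 1] - z[i])
        h0 = z[0] - (-self.long_axis)
        v += math.pi / 3.0 * r[0] ** 2 * h0
        return float(v) * lam ** 3 * 1e-12  # µm³ -> mL

    def cfl_dt_max(self, D: float) -> float:
        """Largest stable explicit time step (ms) for diffusion D (µm²/ms)."""
        if D <= 0:
            return math.inf
        s = 1.0 / float(np.min(self.dy)) ** 2
        if self.n_rings > 1:
            s += 1.0 / float(np.min(self.dmer)) ** 2
        return 1.0 / (2.0 * D * s)

    def laplacian_coefficients(self):
        """(inv_dy2, a_minus, a_plus): per-ring FD weights (1/µm²).

        ``a_minus[i]``/``a_plus[i]`` weight the flux to ring i−1 / i+1 in the
        non-uniform meridional second difference; zero rows encode the
        no-flux boundaries at the apex and base openings.
        """
        inv_dy2 = 1.0 / self.dy ** 2
        a_m = np.zeros(self.n_rings)
        a_p = np.zeros(self.n_rings)
        for i in range(self.n_rings):
            dm = self.dmer[i - 1] if i > 0 else np.nan
            dp = self.dmer[i] if i < self.n_rings - 1 else np.nan
            if i == 0 and self.n_rings > 1:
                dc = dp
                a_p[i] = 1.0 / (dp * dc)
            elif i == self.n_rings - 1 and self.n_rings > 1:
                dc = dm
                a_m[i] = 1.0 / (dm * dc)
            elif self.n_rings > 1:
                dc = 0.5 * (dm + dp)
                a_m[i] = 1.0 / (dm * dc)
                a_p[i] = 1.0 / (dp * dc)
        return inv_dy2, a_m, a_p


# ---------------------------------------------------------------------------
# loading conditions / afterload
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class LoadingConditions:
    """Preload, afterload and the lumped wall-mechanics constants.

    ``preload_stretch`` is the initial uniform stretch ratio λ applied before
    stimulation (the preload length: 0/10/15/20/25%% -> 1.00/1.10/1.15/1.20/
    1.25).  The afterload is a 2-element Windkessel (resistance R_p,
    compliance C) behind an aortic valve resistance; filling is driven by a
    constant filling pressure.  ``force_to_pressure`` maps mean wall tension
    (myofilament force units, divided by the current stretch scale) to cavity
    pressure in mmHg — a single calibration constant documented in the
    methods note.
    """

    preload_stretch: float = 1.0
    filling_pressure: float = 10.0       # mmHg
    windkessel_r: float = 1000.0         # mmHg·ms/mL (peripheral resistance)
    windkessel_c: float = 2.5            # mL/mmHg
    arterial_pressure0: float = 80.0     # mmHg, initial Windkessel pressure
    valve_resistance: float = 80.0       # mmHg·ms/mL
    fill_resistance: float = 50.0        # mmHg·ms/mL
    force_to_pressure: float = 400.0     # mmHg per force unit of wall tension
    passive_kp: float = 0.007            # force units, passive wall stiffness
    passive_bp: float = 10.0             # dimensionless, passive exponent
    force_scale: float = 1.0             # contractility scale (0 = no contraction)

    def __post_init__(self) -> None:
        if self.preload_stretch <= 0:
            raise ValueError("preload_stretch must be > 0")
        if self.windkessel_r <= 0 or self.windkessel_c <= 0 or \
                self.valve_resistance <= 0 or self.fill_resistance <= 0:
            raise ValueError("afterload resistances/compliance must be > 0")
        if self.force_scale < 0:
            raise ValueError("force_scale must be >= 0")

    def passive_tension(self, lam: float) -> float:
        if lam <= 1.0:
            return 0.0
        return self.passive_kp * (math.exp(self.passive_bp * (lam - 1.0)) - 1.0)


# ---------------------------------------------------------------------------
# tissue state and results
# ---------------------------------------------------------------------------
@dataclass
class TissueState:
    """Per-node electrophysiology + sarcomere states and global mechanics."""

    S: np.ndarray            # (NSTATE, n_nodes) myocyte states
    NL: np.ndarray           # (NNL, n_nodes) sarcomere states
    lam: np.ndarray          # (n_rings,) per-ring stretch ratio
    cavity_volume: float     # mL
    cavity_pressure: float   # mmHg
    arterial_pressure: float  # mmHg (Windkessel)
    phase: str = "ivc"
    t: float = 0.0

    @property
    def vm(self) -> np.ndarray:
        return self.S[IV]

    def half_sl(self, half_sl0: float = HALF_SL0) -> np.ndarray:
        return self.lam * half_sl0


@dataclass
class PvRecord:
    """Cavity pressure-volume samples over the simulated beat(s)."""

    time: np.ndarray      # ms
    volume: np.ndarray    # mL
    pressure: np.ndarray  # mmHg
    phase: list = field(default_factory=list)


@dataclass
class PvSummary:
    stroke_volume: float     # mL
    peak_pressure: float     # mmHg
    ejection_fraction: float
    edv: float
    esv: float


@dataclass
class VentricleResult:
    """Sampled voltage history, λ history, PV record and markers."""

    t: np.ndarray              # ms, recording grid
    vm: np.ndarray             # (n_nodes, n_rec)
    lam_eq: np.ndarray         # equatorial-ring λ per mechanics step
    lam_t: np.ndarray          # ms, mechanics grid
    pv: PvRecord
    markers: MarkerTable
    geometry: VentricleGeometry
    loading: LoadingConditions
    repolarization_failed: bool
    dt: float
    final_state: Optional[TissueState] = None


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------
@njit(cache=False)
def _laplacian(V2, inv_dy2, a_m, a_p, out):
    nr, nc = V2.shape
    for i in range(nr):
        for j in range(nc):
            jm = j - 1 if j > 0 else nc - 1
            jp = j + 1 if j < nc - 1 else 0
            lap = (V2[i, jp] + V2[i, jm] - 2.0 * V2[i, j]) * inv_dy2[i]
            if a_p[i] > 0.0:
                lap += (V2[i + 1, j] - V2[i, j]) * a_p[i]
            if a_m[i] > 0.0:
                lap += (V2[i - 1, j] - V2[i, j]) * a_m[i]
            out[i, j] = lap


def diffusion_step(vm_field: np.ndarray, coupling: float,
                   geometry: VentricleGeometry, dt: float) -> np.ndarray:
    """One explicit finite-difference diffusion update of the Vm field.

    ``vm_field`` has shape (n_rings, nodes_per_ring); ``coupling`` is the
    isotropic diffusion coefficient D in µm²/ms.  Periodic circumferentially,
    no-flux across the apex/base openings.  Raises :class:`StabilityError`
    when ``dt`` exceeds the CFL bound, reporting the admissible step.
    """
    vm_field = np.asarray(vm_field, dtype=float)
    if vm_field.shape != (geometry.n_rings, geometry.nodes_per_ring):
        raise GeometryError(
            f"vm_field shape {vm_field.shape} does not match geometry "
            f"({geometry.n_rings}, {geometry.nodes_per_ring})")
    if coupling < 0:
        raise ValueError("coupling must be >= 0")
    if coupling > 0:
        dt_max = geometry.cfl_dt_max(coupling)
        if dt > dt_max:
            raise StabilityError(
                f"dt={dt} ms violates the CFL bound for D={coupling} µm²/ms; "
                f"admissible dt <= {dt_max:.4g} ms")
    inv_dy2, a_m, a_p = geometry.laplacian_coefficients()
    lap = np.empty_like(vm_field)
    _laplacian(vm_field, inv_dy2, a_m, a_p, lap)
    return vm_field + dt * coupling * lap


# ---------------------------------------------------------------------------
# geometry <-> sarcomere coupling
# ---------------------------------------------------------------------------
def update_geometry(cavity_volume: float, geometry: VentricleGeometry,
                    unstressed_volume: Optional[float] = None):
    """Translate cavity volume into HalfSL and λ (applied at the next step).

    The boundary length L_V scales as the cube root of the volume ratio
    (isotropic deformation), so ``HalfSL = L_V / N`` and ``λ = HalfSL /
    HalfSL0 = (V / V0)^(1/3)``.  Returns ``(half_sl, lam, l_v)``.
    """
    if cavity_volume <= 0:
        raise GeometryError(f"cavity volume must be > 0, got {cavity_volume}")
    v0 = unstressed_volume if unstressed_volume is not None else geometry.cavity_volume(1.0)
    lam = (cavity_volume / v0) ** (1.0 / 3.0)
    l_v = lam * geometry.l_v0
    half_sl = l_v / geometry.n_half_sarcomeres
    return half_sl, lam, l_v


# ---------------------------------------------------------------------------
# coupled electromechanics kernel (one mechanics frame)
# ---------------------------------------------------------------------------
@njit(cache=False)
def _advance_frame(S, NL, P, q, sacv, lam_node, half_sl0, D, dt, nsteps,
                   inv_dy2, a_m, a_p, nr, nc, stim_amp, stim_mask,
                   rec_every, rec_buf, lap, vtmp):
    """Advance all nodes ``nsteps`` electro/NL steps with frozen λ field.

    Records Vm into ``rec_buf`` every ``rec_every`` steps (local step 0
    first).  Returns (bad_step, max_overshoot); bad_step = -1 on success.
    """
    n = S.shape[1]
    g_sac = sacv[0]
    max_ov = 0.0
    nrec = 0
    for k in range(nsteps):
        if rec_every > 0 and k % rec_every == 0:
            for i in range(n):
                rec_buf[nrec, i] = S[IV, i]
            nrec += 1
        # diffusion increment on the voltage field
        if D > 0.0:
            V2 = S[IV].reshape(nr, nc)
            _laplacian(V2, inv_dy2, a_m, a_p, lap)
            for i in range(nr):
                for j in range(nc):
                    vtmp[i, j] = dt * D * lap[i, j]
        for i in range(n):
            isac = 0.0
            if g_sac > 0.0 and lam_node[i] > 1.0:
                isac = _isac_node(S[IV, i], lam_node[i], g_sac, sacv[1],
                                  sacv[2], sacv[3])
            istim = stim_amp if stim_mask[i] else 0.0
            ov = _step_one(S, i, P, istim, isac, dt)
            if ov > max_ov:
                max_ov = ov
            if D > 0.0:
                S[IV, i] += vtmp[i // nc, i % nc]
            _nl_step_one(NL, i, S[ICAI, i], lam_node[i] * half_sl0, dt, q)
        if not (-1e6 < S[IV, 0] < 1e6):
            return k, max_ov
    return -1, max_ov


@njit(cache=False)
def _ring_mean_force(NL, lam_node, half_sl0, q, nr, nc, out):
    for i in range(nr):
        s = 0.0
        for j in range(nc):
            idx = i * nc + j
            s += _nl_force(NL, idx, lam_node[idx] * half_sl0, q)
        out[i] = s / nc


# ---------------------------------------------------------------------------
# full coupled simulation
# ---------------------------------------------------------------------------
def _equilibrated_tissue(geometry: VentricleGeometry,
                         loading: LoadingConditions,
                         cell_params: CellParams,
                         sac_params: Optional[SacParams],
                         nl_params: NlParams,
                         dt: float,
                         equilibration: float) -> TissueState:
    """Uniform tissue state: every node at the (sac, λ_preload) rest point."""
    lam_p = loading.preload_stretch
    # each configuration rests at its own preload: quiescent equilibration
    # with the recruitment-gated SAC (silent at λ <= 1, so the unstretched
    # tissue rests at the intrinsic myocyte resting point)
    rest = tnnp.equilibrate(cell_params, sac_params, lam_p,
                            duration=equilibration, dt=dt)
    n = geometry.n_nodes
    S = np.tile(rest.to_vector().reshape(NSTATE, 1), (1, n))
    # sarcomere: relax at diastolic Ca and preload length
    from .myofilament import twitch_from_calcium, SarcomereState
    cai_rest = np.full(int(2000.0 / dt), rest.cai)
    tw = twitch_from_calcium(cai_rest, dt=dt, half_sl=lam_p * geometry.half_sl0,
                             params=nl_params)
    NL = np.tile(tw.final_state.to_vector().reshape(NNL, 1), (1, n))
    lam = np.full(geometry.n_rings, lam_p)
    v_ed = geometry.cavity_volume(lam_p)
    return TissueState(S=S, NL=NL, lam=lam, cavity_volume=v_ed,
                       cavity_pressure=loading.filling_pressure,
                       arterial_pressure=loading.arterial_pressure0,
                       phase="ivc", t=0.0)


def _wall_pressure(ring_force: np.ndarray, lam: np.ndarray,
                   geometry: VentricleGeometry,
                   loading: LoadingConditions) -> float:
    """Lumped Laplace balance: area-weighted wall tension over radius scale."""
    w = geometry.r0 / geometry.r0.sum()
    tension = loading.force_scale * ring_force + np.array(
        [loading.passive_tension(l) for l in lam])
    lam_eq = float(lam[-1])
    return loading.force_to_pressure * float((w * tension).sum()) / lam_eq


def simulate_ventricle(geometry: VentricleGeometry,
                       loading: LoadingConditions,
                       cell_params: Optional[CellParams] = None,
                       sac_params: Optional[SacParams] = None,
                       nl_params: Optional[NlParams] = None,
                       stim_amplitude: float = 15.85,
                       stim_duration: float = 6.0,
                       stim_site: str = "apex-ring",
                       coupling: float = 4.0e6,    # µm²/ms
                       duration: float = 500.0,
                       dt: float = tnnp.DT_DEFAULT,
                       dt_mech: float = 1.0,
                       record_stride: float = 0.2,
                       mechanics: bool = True,
                       equilibration: float = 5000.0,
                       initial_tissue: Optional[TissueState] = None,
                       keep_final_state: bool = False) -> VentricleResult:
    """Coupled electromechanical beat triggered by a 6 ms apex stimulus.

    Per electrophysiology step: monodomain diffusion + ionic model with
    I_SAC(λ); per mechanics step (``dt_mech``): myofilament force aggregated
    per ring -> wall tension -> cavity pressure vs. the afterload phase
    machine -> cavity volume -> L_V -> HalfSL -> λ field used by the *next*
    electrophysiology steps.  With ``mechanics=False`` the geometry stays
    frozen at the preload stretch (no feedback).

    Repolarization failure anywhere in the tissue is reported through
    ``result.repolarization_failed`` (and per-fiber flags), not as an error.
    """
    cell_params = cell_params if cell_params is not None else CellParams()
    nl_params = nl_params if nl_params is not None else NlParams()
    if coupling > 0:
        dt_max = geometry.cfl_dt_max(coupling)
        if dt > dt_max:
            raise StabilityError(
                f"dt={dt} ms violates the CFL bound for D={coupling} µm²/ms; "
                f"admissible dt <= {dt_max:.4g} ms")

    tissue = initial_tissue if initial_tissue is not None else \
        _equilibrated_tissue(geometry, loading, cell_params, sac_params,
                             nl_params, dt, equilibration)
    stim_mask = np.zeros(geometry.n_nodes, dtype=np.bool_)
    if stim_site == "apex-ring":
        stim_mask[:geometry.nodes_per_ring] = True
    elif stim_site == "apex-node":
        stim_mask[geometry.apex_index] = True
    else:
        raise ValueError(f"unknown stim_site {stim_site!r}")
    nr, nc = geometry.n_rings, geometry.nodes_per_ring
    n = geometry.n_nodes
    v0 = geometry.cavity_volume(1.0)
    lam_p = loading.preload_stretch
    v_ed = geometry.cavity_volume(lam_p)

    steps_per_frame = max(1, int(round(dt_mech / dt)))
    rec_every = max(1, int(round(record_stride / dt)))
    if steps_per_frame % rec_every != 0:
        rec_every = steps_per_frame  # fall back to one sample per frame
    n_frames = int(round(duration / (steps_per_frame * dt)))
    recs_per_frame = steps_per_frame // rec_every

    P = cell_params.to_vector()
    q = nl_params.to_vector()
    sacv = tnnp._sac_vector(sac_params)
    inv_dy2, a_m, a_p = geometry.laplacian_coefficients()
    lap = np.empty((nr, nc))
    vtmp = np.empty((nr, nc))
    rec_buf = np.empty((recs_per_frame, n))

    vm_store = np.empty((n_frames * recs_per_frame, n))
    lam_hist = np.empty(n_frames)
    pv_t = np.empty(n_frames)
    pv_v = np.empty(n_frames)
    pv_p = np.empty(n_frames)
    pv_phase = []
    ring_force = np.empty(nr)

    lam_node = np.repeat(tissue.lam, nc)
    for fr in range(n_frames):
        t_fr = fr * steps_per_frame * dt
        stim_on = t_fr < stim_duration and stim_amplitude != 0.0
        bad, ov = _advance_frame(
            tissue.S, tissue.NL, P, q, sacv, lam_node, geometry.half_sl0,
            coupling, dt, steps_per_frame, inv_dy2, a_m, a_p, nr, nc,
            stim_amplitude if stim_on else 0.0, stim_mask,
            rec_every, rec_buf, lap, vtmp)
        if bad >= 0:
            raise NumericalInstabilityError(
                f"non-finite voltage at t={t_fr + bad * dt:.2f} ms (dt={dt})")
        vm_store[fr * recs_per_frame:(fr + 1) * recs_per_frame] = rec_buf

        # ---- mechanics frame -----------------------------------------
        _ring_mean_force(tissue.NL, lam_node, geometry.half_sl0, q, nr, nc,
                         ring_force)
        if mechanics:
            p_wall = _wall_pressure(ring_force, tissue.lam, geometry, loading)
            v = tissue.cavity_volume
            phase = tissue.phase
            p_art = tissue.arterial_pressure
            if phase == "ivc":
                if p_wall >= p_art:
                    phase = "eject"
            if phase == "eject":
                qflow = (p_wall - p_art) / loading.valve_resistance
                if qflow <= 0.0:
                    phase = "ivr"
                else:
                    v = max(v - qflow * dt_mech, 0.05 * v0)
                    p_art += dt_mech * (qflow - p_art / loading.windkessel_r) \
                        / loading.windkessel_c
            if phase == "ivr":
                if p_wall <= loading.filling_pressure:
                    phase = "fill"
            if phase == "fill":
                qfill = (loading.filling_pressure - p_wall) / loading.fill_resistance
                if qfill > 0.0:
                    v = min(v + qfill * dt_mech, v_ed)
                if p_wall >= p_art:
                    phase = "eject"
            # volume -> boundary length -> HalfSL -> λ (used next frame)
            _, lam_new, _ = update_geometry(v, geometry, v0)
            tissue.lam[:] = lam_new
            lam_node = np.repeat(tissue.lam, nc)
            tissue.cavity_volume = v
            tissue.cavity_pressure = p_wall
            tissue.arterial_pressure = p_art
            tissue.phase = phase
        else:
            tissue.cavity_pressure = _wall_pressure(ring_force, tissue.lam,
                                                    geometry, loading)
        tissue.t = (fr + 1) * steps_per_frame * dt
        lam_hist[fr] = tissue.lam[-1]
        pv_t[fr] = tissue.t
        pv_v[fr] = tissue.cavity_volume
        pv_p[fr] = tissue.cavity_pressure
        pv_phase.append(tissue.phase)

    t_rec = np.arange(n_frames * recs_per_frame) * (rec_every * dt)
    markers = extract_markers(t_rec, vm_store.T)
    failed = markers.n_failed > 0
    pv = PvRecord(time=pv_t, volume=pv_v, pressure=pv_p, phase=pv_phase)
    return VentricleResult(
        t=t_rec, vm=vm_store.T, lam_eq=lam_hist, lam_t=pv_t, pv=pv,
        markers=markers, geometry=geometry, loading=loading,
        repolarization_failed=failed, dt=dt,
        final_state=tissue if keep_final_state else None)


# ---------------------------------------------------------------------------
# PV loop analysis
# ---------------------------------------------------------------------------
def generate_pv_loop(pv: PvRecord, min_cycle_ms: float = 400.0) -> PvSummary:
    """Stroke volume, peak pressure and ejection fraction from a PV record.

    Requires the record to span at least ``min_cycle_ms`` (one beat of
    systole and relaxation); shorter histories raise ``ValueError``.
    Stroke volume is EDV − ESV by definition (max/min of the volume trace).
    """
    if pv.time.size == 0 or pv.time[-1] - pv.time[0] < min_cycle_ms:
        raise ValueError(
            f"PV record spans {0 if pv.time.size == 0 else pv.time[-1] - pv.time[0]:.0f} ms; "
            f"a complete cycle (>= {min_cycle_ms} ms) is required")
    edv = float(pv.volume.max())
    esv = float(pv.volume.min())
    sv = edv - esv
    return PvSummary(stroke_volume=sv, peak_pressure=float(pv.pressure.max()),
                     ejection_fraction=sv / edv if edv > 0 else 0.0,
                     edv=edv, esv=esv)
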