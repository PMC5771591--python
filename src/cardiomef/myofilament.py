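"""Myofilament force generation: four-state cross-bridge / troponin-Ca model.

The sarcomere model follows the Negroni–Lascano scheme relating half-sarcomere
dynamics to calcium kinetics.  Troponin sites cycle through four states::

    T  --Y1*Ca-->  TCa  --Y2*Ov(L)-->  TCa~  --Y3-->  T~  --Y4-->  T
       <--Z1--          <--Z2--            <--Z3*Ca--

where ~ marks states with attached (force-generating) cross-bridges.  The
attachment step is modulated by the filament-overlap function Ov(L).  The
ensemble cross-bridge anchor position X relaxes toward the position that
keeps the cross-bridge elongation at its isometric value::

    h = L - X,          dX/dt = B * (h - hc)

and rapid length changes detach bridges at a rate Yd * (dX/dt)^2.  Developed
force is elastic in the attached states:

    F = A * h * ([TCa~] + [T~])        (force units: kPa-equivalent tension)

[Ca2+]_i is an input: the electrophysiology model drives the myofilament
model, with no feedback of mechanics on the calcium transient (no
stretch-dependent troponin affinity).

Load conditions for :func:`nl_step` / :func:`twitch_from_calcium`:

* ``isometric`` — half-sarcomere length held constant; force is the output;
* ``prescribed-length`` — half_sl follows a supplied trajectory;
* ``isotonic-load`` — half_sl evolves against a constant afterload through a
  first-order viscous relaxation.

The rate constants shipped as defaults are a calibration artifact: they are
chosen once so that a 1-Hz human ventricular calcium transient produces a
physiological isometric twitch (peak ~150 ms after the Ca peak, >98%%
relaxed by 500 ms); the full set is documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "NlParams", "SarcomereState", "TwitchResult", "nl_step",
    "twitch_from_calcium", "active_force", "HALF_SL0",
]

HALF_SL0 = 0.97  # µm, resting half-sarcomere length

_MODES = ("isometric", "prescribed-length", "isotonic-load")


@dataclass(frozen=True)
class NlParams:
    """Rate constants and mechanical constants of the myofilament model."""

    tt: float = 0.07        # mM, total troponin regulatory sites
    y1: float = 39.0        # 1/(mM ms), Ca binding to T
    z1: float = 0.03        # 1/ms, Ca unbinding from TCa
    y2: float = 0.006       # 1/ms, cross-bridge attachment (scaled by overlap)
    z2: float = 0.006       # 1/ms, detachment back to TCa
    y3: float = 0.06        # 1/ms, Ca release from attached bridges
    z3: float = 0.8         # 1/(mM ms), Ca rebinding to T~
    y4: float = 0.04        # 1/ms, attached-bridge detachment (T~ -> T)
    yd: float = 8000.0      # ms/µm², strain-dependent detachment gain
    b: float = 1.2          # 1/ms, cross-bridge anchor relaxation rate
    hc: float = 0.005       # µm, isometric cross-bridge elongation
    l_opt: float = 1.12     # µm, overlap optimum half-sarcomere length
    w_ov: float = 0.45      # µm, overlap parabola half-width
    a_force: float = 24000.0  # force units/(µm mM), cross-bridge stiffness

    def __post_init__(self) -> None:
        if self.tt <= 0 or self.b <= 0 or self.hc <= 0:
            raise ValueError("tt, b and hc must be > 0")

    def to_vector(self) -> np.ndarray:
        return np.array([self.y1, self.z1, self.y2, self.z2, self.y3, self.z3,
                         self.y4, self.yd, self.b, self.hc, self.tt,
                         self.l_opt, self.w_ov, self.a_force], dtype=np.float64)


# myofilament state layout for the array kernels
NL_NAMES = ("TCa", "TCaP", "TP", "X")
NNL = 4
(JTCA, JTCAP, JTP, JX) = range(NNL)


@dataclass
class SarcomereState:
    """Half-sarcomere length, troponin/cross-bridge states and force."""

    half_sl: float = HALF_SL0  # µm
    tca: float = 0.0           # mM, Ca-bound troponin (detached)
    tca_p: float = 0.0         # mM, Ca-bound troponin with attached bridges
    t_p: float = 0.0           # mM, attached bridges without Ca
    x: float = HALF_SL0 - 0.005  # µm, cross-bridge anchor position
    t: float = 0.0             # ms

    def __post_init__(self) -> None:
        if self.half_sl <= 0:
            raise ValueError("half_sl must be > 0")

    @property
    def force(self) -> float:
        """Developed (active) force with the default stiffness constant."""
        return active_force(self, NlParams())

    def to_vector(self) -> np.ndarray:
        return np.array([self.tca, self.tca_p, self.t_p, self.x], dtype=np.float64)


def overlap(half_sl, p: NlParams):
    """Filament-overlap factor in [0, 1], parabolic with optimum at ``l_opt``."""
    hs = np.asarray(half_sl, dtype=float)
    ov = 1.0 - ((hs - p.l_opt) / p.w_ov) ** 2
    ov = np.clip(ov, 0.0, 1.0)
    return float(ov) if ov.ndim == 0 else ov


def active_force(state: SarcomereState, p: NlParams) -> float:
    """Developed force A·h·([TCa~]+[T~]) (force units); >= 0 by construction."""
    h = state.half_sl - state.x
    return max(0.0, p.a_force * h * (state.tca_p + state.t_p))


@njit(cache=False)
def _nl_step_one(NL, i, cai, L, dt, q):
    """One step of the myofilament kinetics for node ``i``; L is the current
    half-sarcomere length.  Returns the smallest state value (negative ->
    instability)."""
    tca = NL[JTCA, i]
    tcap = NL[JTCAP, i]
    tp = NL[JTP, i]
    x = NL[JX, i]

    h = L - x
    dxdt = q[8] * (h - q[9])           # B*(h - hc)
    ov = 1.0 - ((L - q[11]) / q[12]) ** 2
    if ov < 0.0:
        ov = 0.0
    elif ov > 1.0:
        ov = 1.0

    t_free = q[10] - tca - tcap - tp
    qb = q[0] * cai * t_free - q[1] * tca
    qa = q[2] * ov * tca - q[3] * tcap
    qr = q[4] * tcap - q[5] * tp * cai
    qd = q[6] * tp
    vd = q[7] * dxdt * dxdt
    qd1 = vd * tp
    qd2 = vd * tcap

    NL[JTCA, i] = tca + dt * (qb - qa)
    NL[JTCAP, i] = tcap + dt * (qa - qr - qd2)
    NL[JTP, i] = tp + dt * (qr - qd - qd1)
    NL[JX, i] = x + dt * dxdt

    mn = NL[JTCA, i]
    if NL[JTCAP, i] < mn:
        mn = NL[JTCAP, i]
    if NL[JTP, i] < mn:
        mn = NL[JTP, i]
    return mn


@njit(cache=False)
def _nl_force(NL, i, L, q):
    f = q[13] * (L - NL[JX, i]) * (NL[JTCAP, i] + NL[JTP, i])
    return f if f > 0.0 else 0.0


@njit(cache=False)
def _nl_run(NL, cai_tr, L_tr, dt, q, force_out):
    """Drive one sarcomere through Cai and length trajectories (same grid)."""
    mn_all = 1.0
    for k in range(cai_tr.shape[0]):
        force_out[k] = _nl_force(NL, 0, L_tr[k], q)
        mn = _nl_step_one(NL, 0, cai_tr[k], L_tr[k], dt, q)
        if mn < mn_all:
            mn_all = mn
    return mn_all


def nl_step(state: SarcomereState, cai: float, load_condition: str = "isometric",
            dt: float = 0.02, params: Optional[NlParams] = None,
            half_sl: Optional[float] = None, load: float = 0.0,
            eta: float = 50.0) -> SarcomereState:
    """Advance the myofilament state one time step.

    Parameters
    ----------
    cai : mM, instantaneous free calcium (>= 0).
    load_condition : "isometric" holds half_sl; "prescribed-length" sets it to
        ``half_sl``; "isotonic-load" relaxes it against a constant ``load``
        with viscosity ``eta`` (force units · ms/µm).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if cai < 0:
        raise ValueError("cai must be >= 0")
    if load_condition not in _MODES:
        raise ValueError(f"unknown load_condition {load_condition!r}; use one of {_MODES}")
    p = params if params is not None else NlParams()
    L = state.half_sl
    if load_condition == "prescribed-length":
        if half_sl is None:
            raise ValueError("prescribed-length mode requires half_sl")
        L = float(half_sl)
    elif load_condition == "isotonic-load":
        f = active_force(state, p)
        L = state.half_sl + dt * (load - f) / eta
        L = max(L, 0.5 * HALF_SL0)
    NL = state.to_vector().reshape(NNL, 1)
    mn = _nl_step_one(NL, 0, cai, L, dt, p.to_vector())
    if mn < 0.0:
        raise RuntimeError(
            f"myofilament state went negative ({mn:.3e}) at t={state.t} ms; "
            f"reduce dt (currently {dt} ms)")
    return SarcomereState(half_sl=L, tca=float(NL[JTCA, 0]),
                          tca_p=float(NL[JTCAP, 0]), t_p=float(NL[JTP, 0]),
                          x=float(NL[JX, 0]), t=state.t + dt)


@dataclass
class TwitchResult:
    """Force / half-sarcomere-length time series from a calcium transient."""

    t: np.ndarray        # ms
    force: np.ndarray    # force units
    half_sl: np.ndarray  # µm
    final_state: SarcomereState


def twitch_from_calcium(cai_trace, dt: float = 0.02,
                        mode: str = "isometric",
                        half_sl_trace=None,
                        half_sl: float = HALF_SL0,
                        params: Optional[NlParams] = None,
                        initial_state: Optional[SarcomereState] = None) -> TwitchResult:
    """Run the sarcomere through a uniformly sampled calcium transient.

    ``cai_trace`` is sampled every ``dt`` ms.  In ``prescribed-length`` mode
    ``half_sl_trace`` (same grid) drives the length; in ``isometric`` mode
    the length is held at ``half_sl``.
    """
    cai_trace = np.asarray(cai_trace, dtype=float)
    if cai_trace.size == 0:
        raise ValueError("empty calcium trace")
    if np.any(cai_trace < 0):
        raise ValueError("cai must be >= 0")
    if mode == "prescribed-length":
        if half_sl_trace is None:
            raise ValueError("prescribed-length mode requires half_sl_trace")
        L_tr = np.asarray(half_sl_trace, dtype=float)
        if L_tr.shape != cai_trace.shape:
            raise ValueError("half_sl_trace must match cai_trace shape")
    elif mode == "isometric":
        L_tr = np.full_like(cai_trace, half_sl)
    else:
        raise ValueError(f"unsupported mode {mode!r} for twitch_from_calcium")
    p = params if params is not None else NlParams()
    st = initial_state if initial_state is not None else SarcomereState(
        half_sl=float(L_tr[0]), x=float(L_tr[0]) - p.hc)
    NL = st.to_vector().reshape(NNL, 1).copy()
    force = np.empty_like(cai_trace)
    mn = _nl_run(NL, cai_trace, L_tr, dt, p.to_vector(), force)
    if mn < 0.0:
        raise RuntimeError(
            f"myofilament state went negative ({mn:.3e}); reduce dt "
            f"(currently {dt} ms)")
    t = np.arange(cai_trace.size) * dt
    final = SarcomereState(half_sl=float(L_tr[-1]), tca=float(NL[JTCA, 0]),
                           tca_p=float(NL[JTCAP, 0]), t_p=float(NL[JTP, 0]),
                           x=float(NL[JX, 0]), t=st.t + cai_trace.size * dt)
    return TwitchResult(t=t, force=force, half_sl=L_tr, final_state=final)
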