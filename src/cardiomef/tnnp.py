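"""Human ventricular myocyte ionic model (mid-myocardial parameter set).

The membrane model follows the 2004 ten Tusscher–Noble–Noble–Panfilov (TNNP)
formulation of the human ventricular action potential: 12 sarcolemmal
currents, intracellular Na+/K+/Ca2+ dynamics with SR uptake/release and
algebraic Ca buffering.  Time stepping is forward Euler on the membrane
voltage and ionic concentrations with Rush–Larsen exponential updates of the
gating variables, at a default time step of 0.02 ms (the Hodgkin–Huxley
gates are far stiffer than the voltage equation, so plain Euler on the gates
is unstable at any practical step).  Only the mid-myocardial (M-cell)
parameter set is provided.

The membrane equation is::

    dVm/dt = -(Iion - Istim)          [mV/ms, currents in pA/pF]

    Iion = INa + INaK + IbNa + IK1 + Ito + IKr + IKs + IpK
         + ICaL + INaCa + IpCa + IbCa + ISAC

where ISAC, the stretch-activated channel current, is supplied externally by
:mod:`cardiomef.sac` (zero when the channel is disabled).  ISAC is treated as
a non-selective lumped current and therefore does not enter the ionic
concentration bookkeeping.

Heart-failure remodeling is expressed as multiplicative factors on the
maximal conductances of Ito, IKs, IK1, INa, ICaL and on the Na+/Ca2+
exchanger scale (:class:`HfModifiers`).

All hot loops are compiled with numba; the public API works with plain
dataclasses and numpy arrays.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

from .sac import SacParams

__all__ = [
    "CellParams", "CellState", "HfModifiers", "StimulusSpec", "CellTrace",
    "compute_ionic_currents", "euler_step", "apply_hf", "equilibrate",
    "run_paced_cell", "InvalidStateError", "NumericalInstabilityError",
    "ParameterError", "CURRENT_NAMES", "STATE_NAMES", "DT_DEFAULT",
]

DT_DEFAULT = 0.02  # ms, forward-Euler time step

# ---------------------------------------------------------------------------
# physical constants and fixed model parameters (37 C, standard extracellular solutions)
# ---------------------------------------------------------------------------
R_GAS = 8314.472      # mJ/(mol K)
TEMP = 310.0          # K
FARADAY = 96485.3415  # C/mol
RTF = R_GAS * TEMP / FARADAY

NA_O = 140.0  # mM
CA_O = 2.0    # mM
K_O = 5.4     # mM

P_KNA = 0.03
KM_K = 1.0
KM_NA = 40.0
KM_NAI = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
ALPHA_NACA = 2.5
KP_CA = 0.0005

# calcium dynamics
V_MAXUP = 0.000425
K_UP = 0.00025
A_REL = 0.016464
B_REL = 0.25
C_REL = 0.008232
V_LEAK = 8e-5
BUF_C = 0.15
K_BUFC = 0.001
BUF_SR = 10.0
K_BUFSR = 0.3
V_C = 0.016404
V_SR = 0.001094
CAPACITANCE = 0.185  # µF, whole-cell capacitance used in the mM/ms conversions

INV_VCF = 1.0 / (V_C * FARADAY)
INV_VCF2 = 1.0 / (2.0 * V_C * FARADAY)

# state vector layout (shared with the tissue integrator)
STATE_NAMES = (
    "Vm", "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "fCa", "g",
    "Nai", "Ki", "Cai", "CaSR",
)
NSTATE = len(STATE_NAMES)
(IV, IM, IH, IJ, IXR1, IXR2, IXS, IR, IS, ID, IF, IFCA, IG,
 INAI, IKI, ICAI, ICASR) = range(NSTATE)

# parameter vector layout
PARAM_NAMES = ("g_na", "g_k1", "g_to", "g_kr", "g_ks", "g_pk", "g_cal",
               "k_naca", "p_nak", "g_pca", "g_bna", "g_bca")
NPARAM = len(PARAM_NAMES)

CURRENT_NAMES = ("I_Na", "I_NaK", "I_bNa", "I_K1", "I_to", "I_Kr", "I_Ks",
                 "I_pK", "I_CaL", "I_NaCa", "I_pCa", "I_bCa", "I_SAC")


class InvalidStateError(ValueError):
    """A state variable is non-finite or out of its physical domain."""


class NumericalInstabilityError(RuntimeError):
    """The forward-Euler integration diverged (NaN/Inf or gate overshoot)."""


class ParameterError(ValueError):
    """An invalid model parameter (e.g. non-positive HF factor)."""


# ---------------------------------------------------------------------------
# dataclasses
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CellParams:
    """Maximal conductances / transporter scales of the M-cell parameter set.

    Units: conductances in nS/pF, ICaL permeability scale in
    cm^3 uF^-1 s^-1 (native formulation units), exchanger/pump scales in
    pA/pF.  ``cm`` is the specific membrane capacitance (µF/cm²); all current
    densities are already normalised per capacitance so it never rescales the
    membrane equation.
    """

    g_na: float = 14.838
    g_k1: float = 5.405
    g_to: float = 0.294
    g_kr: float = 0.096
    g_ks: float = 0.062
    g_pk: float = 0.0146
    g_cal: float = 1.75e-4
    k_naca: float = 1000.0
    p_nak: float = 1.362
    g_pca: float = 0.825
    g_bna: float = 2.9e-4
    g_bca: float = 5.92e-4
    cm: float = 2.0
    cell_type: str = "M"

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.cell_type != "M":
            raise ParameterError("only the mid-myocardial ('M') parameter set is supported")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=np.float64)


@dataclass(frozen=True)
class HfModifiers:
    """Multiplicative heart-failure scale factors (identity = 1.0 each)."""

    f_ito: float = 1.0
    f_iks: float = 1.0
    f_ik1: float = 1.0
    f_ina: float = 1.0
    f_ical: float = 1.0
    f_inaca: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise ParameterError(f"HF factor {f.name} must be > 0, got {v}")

    @property
    def is_identity(self) -> bool:
        return all(getattr(self, f.name) == 1.0 for f in dataclasses.fields(self))


@dataclass(frozen=True)
class StimulusSpec:
    """Rectangular stimulus pulse(s); positive amplitude depolarizes."""

    amplitude: float = 52.0  # pA/pF
    onset: float = 0.0       # ms
    duration: float = 1.0    # ms
    period: Optional[float] = None  # ms; None = single pulse

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ParameterError(f"stimulus duration must be > 0, got {self.duration}")
        if self.period is not None and self.period <= self.duration:
            raise ParameterError("stimulus period must exceed the pulse duration")


@dataclass
class CellState:
    """Full electrophysiological state of one myocyte."""

    vm: float = -86.2
    m: float = 0.0
    h: float = 0.75
    j: float = 0.75
    xr1: float = 0.0
    xr2: float = 1.0
    xs: float = 0.0
    r: float = 0.0
    s: float = 1.0
    d: float = 0.0
    f: float = 1.0
    fca: float = 1.0
    g: float = 1.0
    nai: float = 11.6
    ki: float = 138.3
    cai: float = 0.0002
    casr: float = 0.2
    t: float = 0.0

    _FIELD_ORDER = ("vm", "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d",
                    "f", "fca", "g", "nai", "ki", "cai", "casr")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self._FIELD_ORDER], dtype=np.float64)

    @classmethod
    def from_vector(cls, v: np.ndarray, t: float = 0.0) -> "CellState":
        kw = {name: float(v[i]) for i, name in enumerate(cls._FIELD_ORDER)}
        return cls(t=t, **kw)

    def validate(self) -> None:
        for i, name in enumerate(self._FIELD_ORDER):
            val = getattr(self, name)
            if not math.isfinite(val):
                raise InvalidStateError(f"state variable {STATE_NAMES[i]!r} is non-finite: {val}")
        for name in ("nai", "ki", "cai", "casr"):
            if getattr(self, name) <= 0:
                raise InvalidStateError(f"concentration {name!r} must be > 0")


@dataclass
class CellTrace:
    """Uniformly sampled single-cell recording."""

    t: np.ndarray            # ms
    vm: np.ndarray           # mV
    cai: np.ndarray          # mM
    final_state: CellState
    dt: float
    lam: float
    snapshots: Optional[np.ndarray] = None       # (NSTATE, n_snap)
    snapshot_times: Optional[np.ndarray] = None  # ms


# ---------------------------------------------------------------------------
# numba kernels (operate on the (NSTATE, n) state matrix in place)
# ---------------------------------------------------------------------------
@njit(cache=False)
def _currents_one(S, i, P, isac):
    """All 12 ionic currents of node ``i`` (pA/pF), given external ISAC."""
    V = S[IV, i]
    nai = S[INAI, i]
    ki = S[IKI, i]
    cai = S[ICAI, i]

    ena = RTF * math.log(NA_O / nai)
    ek = RTF * math.log(K_O / ki)
    eks = RTF * math.log((K_O + P_KNA * NA_O) / (ki + P_KNA * nai))
    eca = 0.5 * RTF * math.log(CA_O / cai)

    ina = P[0] * S[IM, i] ** 3 * S[IH, i] * S[IJ, i] * (V - ena)
    ibna = P[10] * (V - ena)

    ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - ek - 200.0)))
    bk1 = (3.0 * math.exp(0.0002 * (V - ek + 100.0))
           + math.exp(0.1 * (V - ek - 10.0))) / (1.0 + math.exp(-0.5 * (V - ek)))
    ik1 = P[1] * math.sqrt(K_O / 5.4) * ak1 / (ak1 + bk1) * (V - ek)

    ito = P[2] * S[IR, i] * S[IS, i] * (V - ek)
    ikr = P[3] * math.sqrt(K_O / 5.4) * S[IXR1, i] * S[IXR2, i] * (V - ek)
    iks = P[4] * S[IXS, i] * S[IXS, i] * (V - eks)
    ipk = P[5] * (V - ek) / (1.0 + math.exp((25.0 - V) / 5.98))

    vv = V if abs(V) > 1e-8 else 1e-8
    e2v = math.exp(2.0 * vv / RTF)
    ical = (P[6] * S[ID, i] * S[IF, i] * S[IFCA, i] * 4.0 * vv
            * (FARADAY / RTF) * (cai * e2v - 0.341 * CA_O) / (e2v - 1.0))

    evg = math.exp(GAMMA * V / RTF)
    evg1 = math.exp((GAMMA - 1.0) * V / RTF)
    inaca = (P[7] * (evg * nai ** 3 * CA_O - evg1 * NA_O ** 3 * cai * ALPHA_NACA)
             / ((KM_NAI ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                * (1.0 + K_SAT * evg1)))

    inak = (P[8] * K_O * nai / ((K_O + KM_K) * (nai + KM_NA))
            / (1.0 + 0.1245 * math.exp(-0.1 * V / RTF)
               + 0.0353 * math.exp(-V / RTF)))

    ipca = P[9] * cai / (KP_CA + cai)
    ibca = P[11] * (V - eca)

    return (ina, inak, ibna, ik1, ito, ikr, iks, ipk, ical, inaca, ipca, ibca)


@njit(cache=False)
def _step_one(S, i, P, istim, isac, dt):
    """Advance node ``i`` one forward-Euler step; returns max gate overshoot."""
    (ina, inak, ibna, ik1, ito, ikr, iks, ipk, ical, inaca, ipca,
     ibca) = _currents_one(S, i, P, isac)
    iion = (ina + inak + ibna + ik1 + ito + ikr + iks + ipk + ical + inaca
            + ipca + ibca + isac)

    V = S[IV, i]
    cai = S[ICAI, i]

    # ---- gate rates --------------------------------------------------
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0))
    tau_m = am * bm

    h_inf = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    tau_h = 1.0 / (ah + bh)

    j_inf = h_inf
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * V) - 6.948e-6 * math.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    tau_j = 1.0 / (aj + bj)

    xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tau_xr1 = axr1 * bxr1

    xr2_inf = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tau_xr2 = axr2 * bxr2

    xs_inf = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 60.0) / 20.0))
    tau_xs = axs * bxs

    r_inf = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * math.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8

    s_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
    tau_s = (85.0 * math.exp(-(V + 45.0) ** 2 / 320.0)
             + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)

    d_inf = 1.0 / (1.0 + math.exp((-5.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    tau_d = ad * bd + gd

    f_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    tau_f = (1125.0 * math.exp(-(V + 27.0) ** 2 / 240.0) + 80.0
             + 165.0 / (1.0 + math.exp((25.0 - V) / 10.0)))

    afca = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    bfca = 0.1 / (1.0 + math.exp((cai - 0.0005) / 0.0001))
    gfca = 0.2 / (1.0 + math.exp((cai - 0.00075) / 0.0008))
    fca_inf = (afca + bfca + gfca + 0.23) / 1.46
    # the raw expression can reach 1.048 at diastolic Ca; cap to keep the
    # gate within [0,1] (ICaL is negligible whenever the cap is active)
    if fca_inf > 1.0:
        fca_inf = 1.0

    if cai < 0.00035:
        g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 16)

    # ---- SR calcium fluxes (computed on the pre-step state) ----------
    casr = S[ICASR, i]
    irel = (A_REL * casr * casr / (B_REL * B_REL + casr * casr) + C_REL) * S[ID, i] * S[IG, i]
    ileak = V_LEAK * (casr - cai)
    iup = V_MAXUP / (1.0 + (K_UP / cai) ** 2)

    # ---- updates: forward Euler on Vm, Rush-Larsen on the gates ------
    # (the HH gates are far stiffer than dt = 0.02 ms — tau_m ~ 1 µs at
    # rest — so they use the exact exponential relaxation toward inf)
    S[IV, i] = V + dt * (-(iion - istim))

    overshoot = 0.0
    S[IM, i] = m_inf + (S[IM, i] - m_inf) * math.exp(-dt / tau_m)
    S[IH, i] = h_inf + (S[IH, i] - h_inf) * math.exp(-dt / tau_h)
    S[IJ, i] = j_inf + (S[IJ, i] - j_inf) * math.exp(-dt / tau_j)
    S[IXR1, i] = xr1_inf + (S[IXR1, i] - xr1_inf) * math.exp(-dt / tau_xr1)
    S[IXR2, i] = xr2_inf + (S[IXR2, i] - xr2_inf) * math.exp(-dt / tau_xr2)
    S[IXS, i] = xs_inf + (S[IXS, i] - xs_inf) * math.exp(-dt / tau_xs)
    S[IR, i] = r_inf + (S[IR, i] - r_inf) * math.exp(-dt / tau_r)
    S[IS, i] = s_inf + (S[IS, i] - s_inf) * math.exp(-dt / tau_s)
    S[ID, i] = d_inf + (S[ID, i] - d_inf) * math.exp(-dt / tau_d)
    S[IF, i] = f_inf + (S[IF, i] - f_inf) * math.exp(-dt / tau_f)

    # Ca-gated gates relax with tau = 2 ms but are frozen when they would
    # recover (inf > current) while the membrane is depolarized (V > -60 mV).
    efca = math.exp(-dt / 2.0)
    if not (fca_inf > S[IFCA, i] and V > -60.0):
        S[IFCA, i] = fca_inf + (S[IFCA, i] - fca_inf) * efca
    if not (g_inf > S[IG, i] and V > -60.0):
        S[IG, i] = g_inf + (S[IG, i] - g_inf) * efca

    for gi in range(IM, IG + 1):
        gv = S[gi, i]
        if gv < 0.0:
            if -gv > overshoot:
                overshoot = -gv
            S[gi, i] = 0.0
        elif gv > 1.0:
            if gv - 1.0 > overshoot:
                overshoot = gv - 1.0
            S[gi, i] = 1.0

    # ---- concentrations (algebraic buffer update, quadratic solve) ----
    ca_current = -(ical + ibca + ipca - 2.0 * inaca) * INV_VCF2 * CAPACITANCE
    ca_sr_current = iup - irel - ileak

    ca_csqn = BUF_SR * casr / (casr + K_BUFSR)
    dcasr = dt * (V_C / V_SR) * ca_sr_current
    bjsr = BUF_SR - ca_csqn - dcasr - casr + K_BUFSR
    cjsr = K_BUFSR * (ca_csqn + dcasr + casr)
    S[ICASR, i] = (math.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0

    ca_buf = BUF_C * cai / (cai + K_BUFC)
    dcai = dt * (ca_current - ca_sr_current)
    bc = BUF_C - ca_buf - dcai - cai + K_BUFC
    cc = K_BUFC * (ca_buf + dcai + cai)
    S[ICAI, i] = (math.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

    S[INAI, i] += dt * (-(ina + ibna + 3.0 * inak + 3.0 * inaca)) * INV_VCF * CAPACITANCE
    S[IKI, i] += dt * (-(ik1 + ito + ikr + iks - 2.0 * inak + ipk - istim)) * INV_VCF * CAPACITANCE

    return overshoot


@njit(cache=False)
def _isac_node(V, lam, g_sac, v_rev, k, alpha):
    return g_sac / (1.0 + k * math.exp(-alpha * (lam - 1.0))) * (V - v_rev)


@njit(cache=False)
def _run_single(S, P, sacv, lam, dt, n_steps, stim_amp, stim_onset,
                stim_dur, stim_period, rec_stride, vm_out, cai_out):
    """Integrate one cell for ``n_steps``; record Vm/Cai every ``rec_stride``.

    Returns (status_step, max_overshoot); status_step == -1 on success,
    otherwise the step index at which a non-finite voltage appeared.
    """
    g_sac = sacv[0]
    max_ov = 0.0
    for k in range(n_steps):
        if k % rec_stride == 0:
            vm_out[k // rec_stride] = S[IV, 0]
            cai_out[k // rec_stride] = S[ICAI, 0]
        tk = k * dt
        istim = 0.0
        if stim_amp != 0.0 and tk >= stim_onset:
            if stim_period > 0.0:
                if (tk - stim_onset) % stim_period < stim_dur:
                    istim = stim_amp
            elif tk < stim_onset + stim_dur:
                istim = stim_amp
        isac = 0.0
        if g_sac > 0.0 and lam > 1.0:
            isac = _isac_node(S[IV, 0], lam, g_sac, sacv[1], sacv[2], sacv[3])
        ov = _step_one(S, 0, P, istim, isac, dt)
        if ov > max_ov:
            max_ov = ov
        V = S[IV, 0]
        if not (-1e6 < V < 1e6):
            return k, max_ov
    return -1, max_ov


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------
def _sac_vector(sac: Optional[SacParams]) -> np.ndarray:
    if sac is None:
        return np.zeros(4, dtype=np.float64)
    return np.array([sac.g_sac, sac.v_rev, sac.k, sac.alpha], dtype=np.float64)


def compute_ionic_currents(state: CellState, params: CellParams,
                           i_sac: float = 0.0) -> dict:
    """All 12 ionic currents plus the supplied ISAC and their sum (pA/pF).

    Returns a dict keyed by current name (see :data:`CURRENT_NAMES`) plus
    ``"I_ion"``, the arithmetic total of the 13 components.
    """
    state.validate()
    if not math.isfinite(i_sac):
        raise InvalidStateError("i_sac is non-finite")
    S = state.to_vector().reshape(NSTATE, 1)
    cur = _currents_one(S, 0, params.to_vector(), i_sac)
    out = dict(zip(CURRENT_NAMES[:12], (float(c) for c in cur)))
    out["I_SAC"] = float(i_sac)
    out["I_ion"] = float(sum(cur) + i_sac)
    return out


def euler_step(state: CellState, params: CellParams, istim: float = 0.0,
               i_sac: float = 0.0, dt: float = DT_DEFAULT) -> CellState:
    """One forward-Euler step of the full cell model.

    Gating variables are clipped into [0, 1] only for round-off-level
    overshoots (< 1e-9); larger overshoots raise
    :class:`NumericalInstabilityError`, as does a non-finite voltage.
    """
    if not (dt > 0):
        raise ParameterError(f"dt must be > 0, got {dt}")
    state.validate()
    S = state.to_vector().reshape(NSTATE, 1).copy()
    ov = _step_one(S, 0, params.to_vector(), istim, i_sac, dt)
    if ov > 1e-9:
        raise NumericalInstabilityError(
            f"gate overshoot {ov:.3e} at t={state.t} ms with dt={dt} ms; reduce dt")
    if not np.all(np.isfinite(S)):
        raise NumericalInstabilityError(
            f"non-finite state after step at t={state.t} ms with dt={dt} ms")
    return CellState.from_vector(S[:, 0], t=state.t + dt)


def apply_hf(params: CellParams, mods: HfModifiers) -> CellParams:
    """Heart-failure remodeling: scale the six named conductances/exchanger.

    Identity modifiers return a parameter set equal to the input; all other
    parameters are untouched.
    """
    return replace(
        params,
        g_to=params.g_to * mods.f_ito,
        g_ks=params.g_ks * mods.f_iks,
        g_k1=params.g_k1 * mods.f_ik1,
        g_na=params.g_na * mods.f_ina,
        g_cal=params.g_cal * mods.f_ical,
        k_naca=params.k_naca * mods.f_inaca,
    )


def _run(state: CellState, params: CellParams, sac: Optional[SacParams],
         lam: float, duration: float, dt: float, stim: Optional[StimulusSpec],
         record_stride: float) -> CellTrace:
    n_steps = int(round(duration / dt))
    rec = max(1, int(round(record_stride / dt)))
    n_rec = (n_steps + rec - 1) // rec
    vm_out = np.empty(n_rec, dtype=np.float64)
    cai_out = np.empty(n_rec, dtype=np.float64)
    S = state.to_vector().reshape(NSTATE, 1).copy()
    if stim is None:
        amp, onset, dur, period = 0.0, 0.0, 1.0, 0.0
    else:
        amp, onset, dur = stim.amplitude, stim.onset, stim.duration
        period = stim.period if stim.period is not None else 0.0
    status, ov = _run_single(S, params.to_vector(), _sac_vector(sac), lam, dt,
                             n_steps, amp, onset, dur, period, rec,
                             vm_out, cai_out)
    if status >= 0:
        raise NumericalInstabilityError(
            f"non-finite voltage at t={status * dt:.3f} ms (dt={dt} ms)")
    if ov > 1e-9:
        raise NumericalInstabilityError(
            f"gate overshoot {ov:.3e} during run (dt={dt} ms); reduce dt")
    t = np.arange(n_rec) * (rec * dt)
    return CellTrace(t=t, vm=vm_out, cai=cai_out,
                     final_state=CellState.from_vector(S[:, 0], t=state.t + n_steps * dt),
                     dt=dt, lam=lam)


def equilibrate(params: CellParams, sac: Optional[SacParams] = None,
                lam: float = 1.0, duration: float = 5000.0,
                dt: float = DT_DEFAULT,
                initial_state: Optional[CellState] = None) -> CellState:
    """Quiescent (unstimulated) relaxation to the resting point.

    With the SAC enabled the resting point depends on the steady stretch
    ``lam`` (the channel passes inward current at rest), so each (params,
    sac, lam) configuration has its own rest state.
    """
    st = initial_state if initial_state is not None else CellState()
    return _run(st, params, sac, lam, duration, dt, None, record_stride=1.0).final_state


def run_paced_cell(params: CellParams, stim: StimulusSpec,
                   sac_config: Optional[SacParams] = None, lam: float = 1.0,
                   duration: float = 1000.0, dt: float = DT_DEFAULT,
                   initial_state: Optional[CellState] = None,
                   record_stride: float = 0.1,
                   equilibration: float = 5000.0) -> CellTrace:
    """Stimulated single-cell run at a fixed steady stretch ``lam``.

    If ``initial_state`` is None the cell is first relaxed quiescently for
    ``equilibration`` ms at the same (sac, lam) configuration, so the run
    starts from its true resting point.  Vm/Cai are returned uniformly
    sampled every ``record_stride`` ms.
    """
    if not (lam >= 0):
        raise ParameterError(f"lam must be >= 0, got {lam}")
    if initial_state is None:
        initial_state = equilibrate(params, sac_config, lam,
                                    duration=equilibration, dt=dt)
    st = dataclasses.replace(initial_state, t=0.0)
    return _run(st, params, sac_config, lam, duration, dt, stim, record_stride)
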