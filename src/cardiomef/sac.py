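"""Stretch-activated channel (SAC) current and stretch-ratio computation.

The SAC is modelled as a linear (ohmic) current gated by a sigmoidal function
of the stretch ratio λ::

    I_SAC = G_SAC * (Vm - V_rev) / (1 + K * exp(-alpha * (λ - 1)))

with λ = HalfSL / HalfSL0, the current half-sarcomere length over the resting
half-sarcomere length.

Unit contract: ``G_SAC`` is expressed in nS/pF, so multiplying by a voltage in
mV yields a current density in pA/pF — the same normalisation used for all the
ionic currents of the myocyte model (current per unit membrane capacitance).

Note that at λ = 1 with K = 1 the effective conductance of the raw law is
G_SAC/2 — the current-voltage relation itself is not silent at rest length
and applies no clamping in λ.  The simulation drivers, however, recruit the
channel only under stretch beyond rest length (:func:`recruited_isac`):
contraction that shortens a fiber below its rest length silences its SAC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SacParams", "stretch_ratio", "compute_isac", "effective_conductance",
           "recruited_isac"]


@dataclass(frozen=True)
class SacParams:
    """SAC parameter set.

    Defaults are the reference values of the formulation: resting
    half-sarcomere length 0.97 µm, K = 1 (current at rest length), alpha = 3
    (stretch sensitivity), reversal potential −20 mV, maximum conductance
    0.025 nS/pF.
    """

    g_sac: float = 0.025  # nS/pF, maximum conductance
    v_rev: float = -20.0  # mV, reversal potential (also called E_SAC)
    k: float = 1.0        # dimensionless, sets the zero-stretch current
    alpha: float = 3.0    # dimensionless, stretch sensitivity
    half_sl0: float = 0.97  # µm, resting half-sarcomere length

    def __post_init__(self) -> None:
        if self.g_sac < 0:
            raise ValueError(f"g_sac must be >= 0, got {self.g_sac}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.half_sl0 <= 0:
            raise ValueError(f"half_sl0 must be > 0, got {self.half_sl0}")

    @property
    def enabled(self) -> bool:
        return self.g_sac > 0.0

    @classmethod
    def disabled(cls) -> "SacParams":
        """A parameter set with the channel switched off (G_SAC = 0)."""
        return cls(g_sac=0.0)


def stretch_ratio(half_sl, half_sl0: float = 0.97):
    """Stretch ratio λ = HalfSL / HalfSL0.

    Parameters
    ----------
    half_sl : float or array
        Current half-sarcomere length (µm). Must be > 0.
    half_sl0 : float
        Resting half-sarcomere length (µm). Must be > 0.

    Returns
    -------
    λ, dimensionless; no clamping is applied.
    """
    half_sl = np.asarray(half_sl, dtype=float)
    if half_sl0 <= 0:
        raise ValueError(f"half_sl0 must be > 0, got {half_sl0}")
    if np.any(half_sl <= 0):
        raise ValueError("half_sl must be > 0")
    out = half_sl / half_sl0
    return float(out) if out.ndim == 0 else out


def effective_conductance(lam, p: SacParams):
    """Stretch-gated conductance G_SAC / (1 + K exp(-alpha (λ-1))), nS/pF.

    Strictly increasing in λ for K > 0, alpha > 0; saturates at G_SAC.
    """
    lam = np.asarray(lam, dtype=float)
    out = p.g_sac / (1.0 + p.k * np.exp(-p.alpha * (lam - 1.0)))
    return float(out) if out.ndim == 0 else out


def compute_isac(vm, lam, p: SacParams):
    """SAC current density (pA/pF) at membrane voltage ``vm`` and stretch ``lam``.

    Negative (inward, depolarizing) when Vm < V_rev; zero at Vm = V_rev and
    whenever G_SAC = 0. Linear in (Vm − V_rev) at fixed λ.
    """
    vm = np.asarray(vm, dtype=float)
    if not np.all(np.isfinite(vm)):
        raise ValueError("vm must be finite")
    lam_arr = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(lam_arr)):
        raise ValueError("lam must be finite")
    out = effective_conductance(lam_arr, p) * (vm - p.v_rev)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def _isac_scalar(vm: float, lam: float, g_sac: float, v_rev: float,
                 k: float, alpha: float) -> float:
    """Scalar fast path used by the integration kernels (no validation)."""
    return g_sac / (1.0 + k * math.exp(-alpha * (lam - 1.0))) * (vm - v_rev)


def recruited_isac(vm, lam, p: SacParams):
    """SAC current as recruited by the loading protocols (pA/pF).

    The channel contributes only when the fiber is stretched beyond its rest
    length: for λ > 1 this is exactly :func:`compute_isac`; at or below rest
    length (λ <= 1) the recruited current is zero.  All simulation drivers use
    this form; :func:`compute_isac` itself is the raw current-voltage law.
    """
    lam_arr = np.asarray(lam, dtype=float)
    out = np.where(lam_arr > 1.0, compute_isac(vm, np.maximum(lam_arr, 1.0), p), 0.0)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out
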