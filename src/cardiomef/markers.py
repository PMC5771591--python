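"""Activation/recovery markers extracted from membrane-voltage traces.

Definitions (single −60 mV threshold for both markers):

* activation time (AT): first *upward* crossing of −60 mV after stimulus
  onset, linearly interpolated between samples;
* recovery time (RT): first *downward* crossing of −60 mV after the AP peak
  (starting the search at the peak avoids stimulus-artifact downward
  crossings), linearly interpolated;
* APD = RT − AT.  Because −60 mV sits at roughly 80% repolarization of the
  human ventricular AP, this duration is reported as APD80.

A fiber that never recovers within the recorded window is flagged
``repolarization_failed``; its RT/APD are undefined (NaN) and it is excluded
from the min/max summaries (with the failure count reported).

First crossing wins when a trace crosses the threshold several times.

The module also provides :func:`synthetic_ap_trace`, a stylized-AP fixture
generator with exactly known AT/RT ground truth, used to unit-test marker
extraction without running the full simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FiberMarkers", "MarkerTable", "detect_at", "detect_rt", "apd",
    "summarize", "extract_markers", "synthetic_ap_trace",
    "AT_THRESHOLD", "RT_THRESHOLD",
]

AT_THRESHOLD = -60.0  # mV
RT_THRESHOLD = -60.0  # mV


def _check_trace(t: np.ndarray, vm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if t.size == 0 or vm.size == 0:
        raise ValueError("empty voltage trace")
    if t.shape != vm.shape:
        raise ValueError(f"time/voltage shape mismatch: {t.shape} vs {vm.shape}")
    return t, vm


def _interp_crossing(t0: float, t1: float, v0: float, v1: float,
                     threshold: float) -> float:
    return t0 + (threshold - v0) / (v1 - v0) * (t1 - t0)


def detect_at(t, vm, threshold: float = AT_THRESHOLD,
              t0: float = 0.0) -> Optional[float]:
    """First upward crossing of ``threshold`` at or after ``t0`` (ms), or None.

    The crossing time is linearly interpolated between the bracketing samples.
    A trace already above threshold at ``t0`` activates at the first sample
    >= ``t0``.
    """
    t, vm = _check_trace(t, vm)
    mask = t >= t0
    if not mask.any():
        return None
    i0 = int(np.argmax(mask))
    if vm[i0] >= threshold:
        return float(t[i0])
    below = vm[i0:] < threshold
    up = np.where(below[:-1] & ~below[1:])[0]
    if up.size == 0:
        return None
    k = i0 + int(up[0])
    return float(_interp_crossing(t[k], t[k + 1], vm[k], vm[k + 1], threshold))


def detect_rt(t, vm, threshold: float = RT_THRESHOLD,
              after: Optional[float] = None) -> Optional[float]:
    """First downward crossing of ``threshold`` after the AP peak (ms), or None.

    ``after`` restricts the peak search to times >= ``after`` (typically the
    activation time); the downward-crossing search always starts at the peak
    sample, so early stimulus artifacts cannot be mistaken for recovery.
    Returns None when the trace never recovers (repolarization failure).
    """
    t, vm = _check_trace(t, vm)
    if after is not None:
        mask = t >= after
        if not mask.any():
            return None
        off = int(np.argmax(mask))
    else:
        off = 0
    pk = off + int(np.argmax(vm[off:]))
    seg = vm[pk:]
    above = seg >= threshold
    down = np.where(above[:-1] & ~above[1:])[0]
    if down.size == 0:
        return None
    k = pk + int(down[0])
    return float(_interp_crossing(t[k], t[k + 1], vm[k], vm[k + 1], threshold))


def apd(at: float, rt: float) -> float:
    """Action potential duration RT − AT (ms); requires RT > AT."""
    if rt <= at:
        raise ValueError(f"rt ({rt}) must exceed at ({at})")
    return rt - at


@dataclass
class FiberMarkers:
    """Per-fiber marker set; NaN marks an undefined value."""

    fiber_id: int
    at: float = np.nan
    rt: float = np.nan
    apd: float = np.nan
    repolarization_failed: bool = False

    @property
    def activated(self) -> bool:
        return np.isfinite(self.at)


@dataclass
class MarkerTable:
    """Per-fiber markers plus global extrema (the results surface).

    Failed fibers (activated but never recovered) are excluded from the
    RT/APD extrema; ``n_failed`` reports how many were excluded.  All-failed
    or no-activation summaries carry NaN ("N/A") extrema.
    """

    fibers: list = field(default_factory=list)
    earliest_at: float = np.nan
    latest_at: float = np.nan
    first_rt: float = np.nan
    last_rt: float = np.nan
    min_apd: float = np.nan
    max_apd: float = np.nan
    n_activated: int = 0
    n_failed: int = 0

    def __len__(self) -> int:
        return len(self.fibers)

    @property
    def any_failed(self) -> bool:
        return self.n_failed > 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "fiber_id": [f.fiber_id for f in self.fibers],
                "AT_ms": [f.at for f in self.fibers],
                "RT_ms": [f.rt for f in self.fibers],
                "APD_ms": [f.apd for f in self.fibers],
                "failed": [f.repolarization_failed for f in self.fibers],
            }
        )


def summarize(fibers: Sequence[FiberMarkers]) -> MarkerTable:
    """Aggregate per-fiber markers into a :class:`MarkerTable`."""
    fibers = list(fibers)
    if len(fibers) == 0:
        raise ValueError("at least one fiber is required")
    tab = MarkerTable(fibers=fibers)
    ats = np.array([f.at for f in fibers if np.isfinite(f.at)])
    tab.n_activated = ats.size
    tab.n_failed = sum(1 for f in fibers if f.repolarization_failed)
    if ats.size:
        tab.earliest_at = float(ats.min())
        tab.latest_at = float(ats.max())
    rts = np.array([f.rt for f in fibers if np.isfinite(f.rt)])
    apds = np.array([f.apd for f in fibers if np.isfinite(f.apd)])
    if rts.size:
        tab.first_rt = float(rts.min())
        tab.last_rt = float(rts.max())
    if apds.size:
        tab.min_apd = float(apds.min())
        tab.max_apd = float(apds.max())
    return tab


def extract_markers(t, vm_traces, threshold: float = AT_THRESHOLD,
                    t0: float = 0.0) -> MarkerTable:
    """Markers for a stack of fiber traces ``vm_traces`` of shape (n_fibers, n_t)."""
    t = np.asarray(t, dtype=float)
    vm_traces = np.atleast_2d(np.asarray(vm_traces, dtype=float))
    fibers = []
    for i in range(vm_traces.shape[0]):
        fm = FiberMarkers(fiber_id=i)
        at = detect_at(t, vm_traces[i], threshold=threshold, t0=t0)
        if at is not None:
            fm.at = at
            rt = detect_rt(t, vm_traces[i], threshold=threshold, after=at)
            if rt is None:
                fm.repolarization_failed = True
            else:
                fm.rt = rt
                fm.apd = apd(at, rt)
        fibers.append(fm)
    return summarize(fibers)


def synthetic_ap_trace(at: float = 10.0, rt: float = 360.0,
                       duration: float = 600.0, dt: float = 0.5,
                       v_rest: float = -85.0, v_peak: float = 35.0,
                       upstroke: float = 1.0, threshold: float = AT_THRESHOLD,
                       repolarization_failure: bool = False):
    """Stylized action potential with exactly known marker ground truth.

    Piecewise-linear shape: rest until the upstroke (placed so the upward
    −60 mV crossing falls exactly at ``at``), a plateau at ``v_peak`` ending
    in a linear repolarization ramp whose downward −60 mV crossing falls
    exactly at ``rt``, then rest.  With ``repolarization_failure`` the trace
    depolarizes and stays above threshold for the rest of the window.

    Returns ``(t, vm)``; linear interpolation of the samples recovers AT and
    RT exactly (to floating-point precision) at any sampling stride that
    keeps at least one sample per linear segment.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be > 0")
    if not repolarization_failure and rt <= at:
        raise ValueError("rt must exceed at")
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    # upstroke start so that the threshold crossing sits exactly at `at`
    frac_up = (threshold - v_rest) / (v_peak - v_rest)
    t_up0 = at - frac_up * upstroke
    t_up1 = t_up0 + upstroke
    if repolarization_failure:
        vm = np.interp(t, [0.0, t_up0, t_up1, duration],
                       [v_rest, v_rest, v_peak, (v_peak + threshold) / 2.0])
        return t, vm
    # repolarization ramp of fixed slope placed so the downward crossing is at `rt`
    ramp = 50.0  # ms from v_peak to v_rest
    frac_dn = (v_peak - threshold) / (v_peak - v_rest)
    t_dn0 = rt - frac_dn * ramp
    t_dn1 = t_dn0 + ramp
    if t_dn0 <= t_up1:
        raise ValueError("rt too close to at for the requested shape")
    vm = np.interp(t, [0.0, t_up0, t_up1, t_dn0, t_dn1, duration],
                   [v_rest, v_rest, v_peak, v_peak, v_rest, v_rest])
    return t, vm
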