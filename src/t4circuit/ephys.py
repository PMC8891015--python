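"""Current- and voltage-clamp analytics.

Input resistance from hyperpolarizing current steps, time-locked input
resistance from repeated sweeps at different holding currents, resting-
potential screening, derivative-based temporal alignment, linear leak
subtraction and the voltage-modulation amplitude dV_m.  All metrics
assume traces resampled to a common 1 kHz time base; hyperpolarizing
currents are negative and resistances positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoltageTrace",
    "EpisodeSet",
    "input_resistance_steps",
    "timelocked_resistance",
    "resting_potential",
    "align_by_derivative",
    "leak_subtract",
    "delta_vm",
]


@dataclass
class VoltageTrace:
    """Membrane potential in mV on a uniform time base."""

    v_mv: np.ndarray
    fs_hz: float = 1000.0
    holding_pa: float = 0.0
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.v_mv = np.asarray(self.v_mv, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.v_mv.size) / self.fs_hz


@dataclass
class EpisodeSet:
    """Repeated identical-stimulus sweeps at varying holding currents."""

    sweeps: list[VoltageTrace]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValueError("episode set must contain sweeps")
        lengths = {s.v_mv.size for s in self.sweeps}
        if len(lengths) != 1:
            raise ValueError("all sweeps must have the same length")

    @property
    def holding_pa(self) -> np.ndarray:
        return np.array([s.holding_pa for s in self.sweeps])

    @property
    def fs_hz(self) -> float:
        return self.sweeps[0].fs_hz

    def voltages(self) -> np.ndarray:
        """Sweep-by-time voltage matrix, mV."""
        return np.stack([s.v_mv for s in self.sweeps])


def input_resistance_steps(currents_pa, delta_v_mv) -> float:
    """Input resistance (GΩ) from step currents and steady voltage changes.

    Least-squares slope of dV (mV) on I (pA); with currents in pA and
    voltages in mV the slope is directly in GΩ.  Invariant to the order
    of the steps and to a common voltage offset.
    """
    i = np.asarray(currents_pa, dtype=float)
    v = np.asarray(delta_v_mv, dtype=float)
    if i.size < 2 or i.size != v.size:
        raise ValueError("need >= 2 matching current/voltage pairs")
    if np.ptp(i) == 0:
        raise ValueError("current steps are all identical")
    slope, _ = np.polyfit(i, v, 1)
    return float(slope)


def timelocked_resistance(
    episodes: EpisodeSet,
    smooth_sd_ms: float = 13.0,
    smooth: bool = True,
) -> np.ndarray:
    """Input resistance versus time (GΩ) from holding-current sweeps.

    At every time point the voltages across sweeps are regressed onto
    the holding currents (with intercept); the slope is the momentary
    input resistance.  For exactly two holding currents this reduces to
    dV_m / dI.  The trace is then smoothed with a Gaussian filter
    (default 13 ms s.d.).
    """
    i = episodes.holding_pa
    if np.unique(i).size < 2:
        raise ValueError("need >= 2 distinct holding currents")
    v = episodes.voltages()                  # (n_sweeps, n_t)
    i_c = i - i.mean()
    slope = (i_c @ v) / np.dot(i_c, i_c)     # per-time-point OLS slope
    if smooth and smooth_sd_ms > 0:
        slope = ndimage.gaussian_filter1d(
            slope, smooth_sd_ms * 1e-3 * episodes.fs_hz, mode="nearest")
    return slope


def resting_potential(trace_mv, criterion_mv: float = -25.0) -> tuple[float, bool]:
    """Resting potential and inclusion flag.

    The most negative potential of the dark, zero-holding trace is taken
    as the resting potential; the cell is accepted only if it is strictly
    more negative than ``criterion_mv``.
    """
    v = np.asarray(trace_mv, dtype=float)
    if v.size == 0:
        raise ValueError("empty trace")
    vrest = float(v.min())
    return vrest, vrest < criterion_mv


class UndefinedOffset(ValueError):
    """Raised when traces are flat and the alignment offset is undefined."""


def align_by_derivative(
    traces: list[np.ndarray],
    template: np.ndarray,
    fs_hz: float = 1000.0,
    lowpass_sd_ms: float = 50.0,
) -> np.ndarray:
    """Per-trace time offsets (s) maximizing derivative cross-correlation.

    Each trace and the template are Gaussian low-pass filtered, then
    differentiated; the integer-sample lag maximizing their cross-
    correlation is returned (positive offset = trace lags the template).
    """
    def deriv(x):
        sm = ndimage.gaussian_filter1d(np.asarray(x, float),
                                       lowpass_sd_ms * 1e-3 * fs_hz,
                                       mode="nearest")
        return np.diff(sm)

    dt_template = deriv(template)
    if np.allclose(dt_template, 0):
        raise UndefinedOffset("flat template")
    offsets = np.empty(len(traces))
    for k, tr in enumerate(traces):
        d = deriv(tr)
        if np.allclose(d, 0):
            raise UndefinedOffset(f"flat trace {k}")
        xc = np.correlate(d, dt_template, mode="full")
        lag = int(np.argmax(xc)) - (dt_template.size - 1)
        offsets[k] = lag / fs_hz
    return offsets


def leak_subtract(
    i_pa: np.ndarray,
    v_mv: np.ndarray,
    prepulse: slice,
) -> tuple[np.ndarray, float, float]:
    """Subtract the linear leak current fitted on a pre-pulse window.

    ``i_pa`` and ``v_mv`` are the clamp current and command voltage over
    time.  A line ``I = a + b V`` is fitted within ``prepulse`` (which
    must be free of synaptic events) and subtracted from the whole
    sweep.  Returns ``(evoked_pa, a, b)`` where ``b`` is the leak
    conductance in nS.  A warning is emitted if the pre-pulse residual
    variance suggests events in the window.
    """
    i = np.asarray(i_pa, dtype=float)
    v = np.asarray(v_mv, dtype=float)
    iw, vw = i[prepulse], v[prepulse]
    if iw.size < 2:
        raise ValueError("pre-pulse window too short")
    if np.ptp(vw) > 0:
        b, a = np.polyfit(vw, iw, 1)
    else:
        b, a = 0.0, float(np.mean(iw))
    resid = iw - (a + b * vw)
    if np.std(resid) > 0.05 * max(np.std(iw), 1e-12):
        import warnings
        warnings.warn("pre-pulse window may contain synaptic events",
                      RuntimeWarning, stacklevel=2)
    return i - (a + b * v), float(a), float(b)


def delta_vm(trace_mv) -> float:
    """Voltage-modulation amplitude: max minus min of the trace, mV."""
    v = np.asarray(trace_mv, dtype=float)
    if v.size == 0:
        raise ValueError("empty trace")
    return float(np.ptp(v))
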