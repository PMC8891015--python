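"""Passive single-compartment model of a T4 neuron.

T4 cells receive five columnar input classes: glutamatergic Mi9
(inhibitory through GluClα, tonically active in darkness), cholinergic
Mi1 and Tm3 (excitatory), and GABAergic Mi4 and C3 (inhibitory, delayed).
Each presynaptic membrane-voltage trace is min-max normalized and passed
through a rectilinear transfer function (threshold + gain) to yield a
conductance relative to the leak.  Because the cell is electrically
compact and capacitive currents are small and fast relative to synaptic
ones, the membrane potential is the instantaneous conductance-weighted
mean of the reversal potentials::

    V_m = (E_Glu g_Mi9 + E_ACh (g_Tm3 + g_Mi1) + E_GABA (g_Mi4 + g_C3)
           + E_leak g_leak) / (g_Mi9 + g_Tm3 + g_Mi1 + g_Mi4 + g_C3 + g_leak)

Multiplying every conductance (including the leak) by a common factor
leaves V_m unchanged — only ratios to g_leak are physically meaningful.

Direction is emulated by time-shifting conductances: for an edge moving
at angle phi (0 = preferred direction) and velocity v across columns
separated by the inter-ommatidial angle theta, Mi9 is advanced and
Mi4/C3 are delayed by ``dt = theta * cos(phi) / v`` relative to Mi1/Tm3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

CLASSES = ("Mi9", "Tm3", "Mi1", "Mi4", "C3")
#: classes pooled onto each reversal potential
GLU_CLASSES = ("Mi9",)
ACH_CLASSES = ("Tm3", "Mi1")
GABA_CLASSES = ("Mi4", "C3")

__all__ = [
    "CLASSES",
    "SynapticParams",
    "FITTED_PARAMS",
    "normalize_inputs",
    "transfer",
    "motion_delay",
    "conductances",
    "simulate_vm",
    "predicted_input_resistance",
    "linearity_index",
    "tuning_prediction",
    "shift_trace",
]


@dataclass
class SynapticParams:
    """Free parameters of the T4 point model plus fixed reversal potentials.

    Gains and thresholds act on min-max-normalized presynaptic voltages;
    conductances are dimensionless, relative to an arbitrary reference
    (only ratios to ``g_leak`` matter).  Reversal potentials are in mV.
    """

    gains: dict[str, float]
    thresholds: dict[str, float]
    e_leak: float = -65.0
    g_leak: float = 0.5
    e_glu: float = -71.0
    e_ach: float = -21.0
    e_gaba: float = -68.0

    def __post_init__(self) -> None:
        for c in CLASSES:
            if c not in self.gains or c not in self.thresholds:
                raise ValueError(f"missing gain/threshold for class {c}")
            if self.gains[c] < 0:
                raise ValueError(f"gain for {c} must be >= 0")
            if not (0.0 <= self.thresholds[c] <= 1.0):
                raise ValueError(f"threshold for {c} must lie in [0, 1]")
        if self.g_leak <= 0:
            raise ValueError("g_leak must be positive")
        for e in (self.e_leak, self.e_glu, self.e_ach, self.e_gaba):
            if not np.isfinite(e):
                raise ValueError("reversal potentials must be finite")

    def reversal(self, cls: str) -> float:
        if cls in GLU_CLASSES:
            return self.e_glu
        if cls in ACH_CLASSES:
            return self.e_ach
        if cls in GABA_CLASSES:
            return self.e_gaba
        raise KeyError(cls)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynapticParams":
        return cls(**d)

    def copy(self, **updates) -> "SynapticParams":
        out = replace(self)
        out.gains = dict(self.gains)
        out.thresholds = dict(self.thresholds)
        for k, v in updates.items():
            setattr(out, k, v)
        return out


#: Fitted parameter set used for all forward simulations (and as the
#: ground truth of the synthetic-data generator).
FITTED_PARAMS = SynapticParams(
    gains={"Mi9": 0.92, "Tm3": 0.35, "Mi1": 0.65, "Mi4": 1.10, "C3": 1.49},
    thresholds={"Mi9": 0.20, "Tm3": 0.35, "Mi1": 0.88, "Mi4": 0.44, "C3": 0.70},
    e_leak=-65.0,
    g_leak=0.50,
)


def normalize_inputs(
    traces: dict[str, dict[str, np.ndarray]],
) -> dict[str, dict[str, np.ndarray]]:
    """Joint min-max normalization per input class across stimulus conditions.

    ``traces[class][condition]`` is a voltage trace in mV.  For each class
    a single minimum and maximum over *all* of its conditions maps every
    trace into [0, 1], so amplitude ratios between conditions are
    retained.  A class whose traces are all flat is degenerate and raises.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for cls, conds in traces.items():
        if not conds:
            raise ValueError(f"no stimulus conditions for class {cls}")
        lo = min(float(np.min(v)) for v in conds.values())
        hi = max(float(np.max(v)) for v in conds.values())
        if hi <= lo:
            raise ValueError(f"flat traces for class {cls}: max == min")
        out[cls] = {k: (np.asarray(v, float) - lo) / (hi - lo) for k, v in conds.items()}
    return out


def transfer(
    v_norm: np.ndarray,
    threshold: float,
    gain: float,
    form: str = "relu",
) -> np.ndarray:
    """Rectilinear voltage-to-conductance transfer.

    ``form='relu'`` (default) gives the continuous form
    ``g = gain * max(0, v - threshold)``; ``form='jump'`` gives
    ``g = gain * v`` above threshold and 0 at or below it.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    v = np.asarray(v_norm, dtype=float)
    if form == "relu":
        return gain * np.maximum(0.0, v - threshold)
    if form == "jump":
        return np.where(v > threshold, gain * v, 0.0)
    raise ValueError(f"unknown transfer form {form!r}")


def motion_delay(
    phi_deg: float,
    theta_deg: float = 4.8,
    velocity_deg_s: float = 30.0,
) -> float:
    """Columnar time shift dt = theta * cos(phi) / v in seconds.

    phi is the stimulus direction relative to the preferred direction.
    Positive dt advances Mi9 and delays Mi4/C3 relative to Mi1/Tm3.
    """
    if velocity_deg_s <= 0:
        raise ValueError("velocity must be positive")
    return theta_deg * np.cos(np.deg2rad(phi_deg)) / velocity_deg_s


def shift_trace(x: np.ndarray, shift_s: float, fs_hz: float) -> np.ndarray:
    """Shift a trace in time by ``shift_s`` (positive = later), edge-padded."""
    x = np.asarray(x, dtype=float)
    n = int(round(shift_s * fs_hz))
    if n == 0:
        return x.copy()
    out = np.empty_like(x)
    if n > 0:
        out[n:] = x[:-n] if n < x.size else x[0]
        out[:n] = x[0]
    else:
        out[:n] = x[-n:]
        out[n:] = x[-1]
    return out


def conductances(
    v_norm: dict[str, np.ndarray],
    params: SynapticParams,
    form: str = "relu",
) -> dict[str, np.ndarray]:
    """Apply the per-class transfer function to normalized voltages."""
    return {
        c: transfer(v_norm[c], params.thresholds[c], params.gains[c], form=form)
        for c in CLASSES
    }


def _check_common_base(g: dict[str, np.ndarray]) -> int:
    lengths = {np.asarray(v).shape for v in g.values()}
    if len(lengths) != 1:
        raise ValueError("conductance traces must share a time base")
    return next(iter(lengths))[0] if next(iter(lengths)) else 0


def simulate_vm(g: dict[str, np.ndarray], params: SynapticParams) -> np.ndarray:
    """Membrane potential of the point model, in mV.

    ``g`` maps each input class to a non-negative conductance trace on a
    common time base.  The result is the conductance-weighted mean of the
    reversal potentials and therefore always lies between the smallest
    and largest reversal potential involved.
    """
    _check_common_base(g)
    num = params.e_leak * params.g_leak
    den = float(params.g_leak)
    num = num + sum(params.reversal(c) * np.asarray(g[c], float) for c in CLASSES)
    den = den + sum(np.asarray(g[c], float) for c in CLASSES)
    if np.any(den <= 0):
        raise ValueError("total conductance must be positive everywhere")
    return num / den


def total_conductance(g: dict[str, np.ndarray], params: SynapticParams) -> np.ndarray:
    """Total (synaptic + leak) relative conductance trace."""
    return params.g_leak + sum(np.asarray(g[c], float) for c in CLASSES)


def predicted_input_resistance(
    g: dict[str, np.ndarray],
    params: SynapticParams,
    baseline: slice | None = None,
) -> np.ndarray:
    """Relative input resistance R(t) = g_total(baseline) / g_total(t).

    ``baseline`` selects the epoch (default: first sample) whose mean
    total conductance defines R = 1.  Values above 1 mark moments when
    the total conductance drops below its baseline — the resistance
    increase that accompanies release from tonic shunting inhibition.
    """
    gt = total_conductance(g, params)
    if baseline is None:
        baseline = slice(0, 1)
    g0 = float(np.mean(gt[baseline]))
    if not np.isfinite(g0) or gt[baseline].size == 0:
        raise ValueError("empty baseline epoch")
    return g0 / gt


def linearity_index(
    params: SynapticParams,
    g_exc: float | np.ndarray = 1.0,
    g_inh_tonic: float | np.ndarray = 1.0,
    e_exc: float | None = None,
    e_inh: float | None = None,
) -> float | np.ndarray:
    """Supralinearity of excitation coinciding with release from inhibition.

    The cell rests with a tonic inhibitory conductance ``g_inh_tonic``
    (reversal ``e_inh``, default E_Glu).  Three events are compared
    against that baseline: excitation alone (``g_exc`` at ``e_exc``,
    default E_ACh, inhibition still present), release alone (inhibition
    drops to zero), and the coincidence of both.  The index is::

        dV(coincident) - [dV(excitation alone) + dV(release alone)]

    in mV; positive means supralinear.  Accepts scalars or broadcastable
    arrays for the two conductances.
    """
    e_exc = params.e_ach if e_exc is None else e_exc
    e_inh = params.e_glu if e_inh is None else e_inh
    gl, el = params.g_leak, params.e_leak
    ge = np.asarray(g_exc, dtype=float)
    gi = np.asarray(g_inh_tonic, dtype=float)

    def v(ge_, gi_):
        return (e_exc * ge_ + e_inh * gi_ + el * gl) / (ge_ + gi_ + gl)

    v_base = v(0.0, gi)
    dv_exc = v(ge, gi) - v_base
    dv_rel = v(0.0, 0.0 * gi) - v_base
    dv_coinc = v(ge, 0.0 * gi) - v_base
    idx = dv_coinc - (dv_exc + dv_rel)
    return float(idx) if idx.ndim == 0 else idx


def tuning_prediction(
    presyn_mv: dict[str, np.ndarray],
    params: SynapticParams,
    fs_hz: float = 1000.0,
    directions_deg: np.ndarray | None = None,
    theta_deg: float = 4.8,
    velocity_deg_s: float = 30.0,
    baseline_s: float = 0.2,
    form: str = "relu",
    already_normalized: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict the directional tuning curve from PD-aligned input traces.

    ``presyn_mv`` holds one trace per input class, temporally aligned as
    during motion at ``velocity_deg_s`` through a common receptive-field
    position.  For each direction phi the Mi9 conductance is advanced and
    the Mi4/C3 conductances delayed by ``motion_delay(phi)``, the model is
    simulated, and the response is the peak depolarization above the
    pre-stimulus baseline (mean of the first ``baseline_s`` seconds).

    Returns ``(directions_deg, response_mv)``.
    """
    if directions_deg is None:
        directions_deg = np.arange(0.0, 360.0, 10.0)
    directions_deg = np.asarray(directions_deg, dtype=float)
    if directions_deg.size == 0:
        raise ValueError("direction list must not be empty")
    if already_normalized:
        v_norm = {c: np.asarray(presyn_mv[c], float) for c in CLASSES}
    else:
        v_norm = {c: v["edge"] for c, v in
                  normalize_inputs({c: {"edge": presyn_mv[c]} for c in CLASSES}).items()}
    g0 = conductances(v_norm, params, form=form)
    n_base = max(1, int(round(baseline_s * fs_hz)))
    responses = np.empty_like(directions_deg)
    for i, phi in enumerate(directions_deg):
        dt = motion_delay(phi, theta_deg, velocity_deg_s)
        g = dict(g0)
        g["Mi9"] = shift_trace(g0["Mi9"], -dt, fs_hz)   # advanced
        g["Mi4"] = shift_trace(g0["Mi4"], +dt, fs_hz)   # delayed
        g["C3"] = shift_trace(g0["C3"], +dt, fs_hz)
        vm = simulate_vm(g, params)
        responses[i] = np.max(vm) - np.mean(vm[:n_base])
    return directions_deg, responses
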