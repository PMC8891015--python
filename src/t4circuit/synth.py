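"""Synthetic electrophysiology generator.

Emulates the statistical structure of in vivo recordings from the five
columnar T4 input classes and from T4 itself, so every analysis stage
can be exercised and scored without any recorded data.

The presynaptic generator is deliberately simple: each class responds to
the luminance inside a Gaussian receptive field through a latency-
shifted difference-of-exponentials filter, signed by its polarity.
Glutamatergic Mi9 is ON-hyperpolarizing and tonically depolarized in
darkness (its conductance provides the tonic shunt); cholinergic
Mi1/Tm3 are ON-depolarizing; GABAergic Mi4/C3 are ON-depolarizing with
a longer latency (the delayed inhibition).  Receptive-field centres are
staggered along the preferred-direction axis at the inter-ommatidial
spacing of 4.8 deg, with Mi9 upstream (so that its response is advanced
during preferred-direction motion) and Mi4/C3 downstream.

T4 episodes are forward simulations of the single-compartment model on
these inputs, offset by holding current times the momentary input
resistance, plus additive white Gaussian voltage noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import point_model as pm
from .ephys import EpisodeSet, VoltageTrace
from .stimuli import StimulusMovie

__all__ = [
    "InputClassSpec",
    "GroundTruth",
    "default_input_specs",
    "default_ground_truth",
    "synth_presyn_response",
    "presyn_v_norm",
    "synth_t4_vm",
    "synth_t4_episode_set",
    "synth_population",
]

#: mean wild-type dark input resistance used as synthetic ground truth, GOhm
BASELINE_RIN_GOHM = 5.28


@dataclass
class InputClassSpec:
    """Generative parameters of one presynaptic input class."""

    class_name: str
    polarity: str                       # 'ON-depolarizing' | 'ON-hyperpolarizing'
    latency_ms: float
    kernel_time_constants_ms: tuple[float, float] = (20.0, 100.0)  # (rise, decay)
    rf_center_deg: tuple[float, float] = (0.0, 0.0)                # (azim, elev)
    rf_width_deg: float = 4.0
    tonic_level_mV: float = -60.0
    amplitude_mV: float = 12.0
    noise_sd_mV: float = 0.5

    def __post_init__(self) -> None:
        if self.polarity not in ("ON-depolarizing", "ON-hyperpolarizing"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.rf_width_deg <= 0:
            raise ValueError("rf_width must be positive")
        r, d = self.kernel_time_constants_ms
        if not (0 < r < d):
            raise ValueError("kernel needs 0 < rise < decay")

    @property
    def sign(self) -> float:
        return -1.0 if self.polarity == "ON-hyperpolarizing" else 1.0

    @property
    def v_range_mv(self) -> tuple[float, float]:
        """Nominal (min, max) of the response, used for normalization."""
        if self.sign < 0:
            return self.tonic_level_mV - self.amplitude_mV, self.tonic_level_mV
        return self.tonic_level_mV, self.tonic_level_mV + self.amplitude_mV


def default_input_specs(
    pd_deg: float = 0.0,
    center_deg: tuple[float, float] = (28.0, 28.0),
    columnar_offset_deg: float = 4.8,
    noise_sd_mV: float = 0.5,
) -> dict[str, InputClassSpec]:
    """Canonical five-class detector centred at ``center_deg``.

    Offsets lie along the PD axis: Mi9 one column upstream of motion in
    the preferred direction, Mi4 and C3 one column downstream, Mi1/Tm3
    on the home column.  Mi4/C3 carry the longer latency.
    """
    phi = np.deg2rad(pd_deg)
    ux, uy = np.cos(phi), np.sin(phi)

    def at(offset: float) -> tuple[float, float]:
        return (center_deg[0] + offset * ux, center_deg[1] + offset * uy)

    # within-pair kernels and widths differ so each class carries a
    # distinct temporal fingerprint (Tm3 more transient and wider-field
    # than Mi1, C3 more transient than Mi4), as in recorded responses
    return {
        "Mi9": InputClassSpec("Mi9", "ON-hyperpolarizing", latency_ms=30.0,
                              kernel_time_constants_ms=(20.0, 100.0),
                              rf_center_deg=at(-columnar_offset_deg),
                              rf_width_deg=4.0, tonic_level_mV=-50.0,
                              amplitude_mV=10.0, noise_sd_mV=noise_sd_mV),
        "Mi1": InputClassSpec("Mi1", "ON-depolarizing", latency_ms=30.0,
                              kernel_time_constants_ms=(20.0, 100.0),
                              rf_center_deg=at(0.0),
                              rf_width_deg=4.0, tonic_level_mV=-60.0,
                              amplitude_mV=15.0, noise_sd_mV=noise_sd_mV),
        "Tm3": InputClassSpec("Tm3", "ON-depolarizing", latency_ms=30.0,
                              kernel_time_constants_ms=(8.0, 45.0),
                              rf_center_deg=at(0.0),
                              rf_width_deg=6.5, tonic_level_mV=-58.0,
                              amplitude_mV=14.0, noise_sd_mV=noise_sd_mV),
        "Mi4": InputClassSpec("Mi4", "ON-depolarizing", latency_ms=150.0,
                              kernel_time_constants_ms=(30.0, 160.0),
                              rf_center_deg=at(+columnar_offset_deg),
                              rf_width_deg=4.0, tonic_level_mV=-62.0,
                              amplitude_mV=12.0, noise_sd_mV=noise_sd_mV),
        "C3": InputClassSpec("C3", "ON-depolarizing", latency_ms=150.0,
                             kernel_time_constants_ms=(12.0, 70.0),
                             rf_center_deg=at(+columnar_offset_deg),
                             rf_width_deg=5.0, tonic_level_mV=-61.0,
                             amplitude_mV=12.0, noise_sd_mV=noise_sd_mV),
    }


@dataclass
class GroundTruth:
    """Bundles the generative state so recovery analyses can be scored."""

    synaptic_params: pm.SynapticParams = field(
        default_factory=lambda: pm.FITTED_PARAMS.copy())
    input_specs: dict[str, InputClassSpec] = field(
        default_factory=default_input_specs)
    seed: int = 0


def default_ground_truth(seed: int = 0, **spec_kwargs) -> GroundTruth:
    return GroundTruth(pm.FITTED_PARAMS.copy(),
                       default_input_specs(**spec_kwargs), seed)


def _local_luminance(movie: StimulusMovie, spec: InputClassSpec) -> np.ndarray:
    """Gaussian-RF-weighted luminance per frame."""
    cx, cy = spec.rf_center_deg
    if not movie.contains((cx, cy)):
        raise ValueError(
            f"rf centre {spec.rf_center_deg} outside movie extent {movie.extent_deg}")
    az, el = movie.azimuths, movie.elevations
    wx = np.exp(-0.5 * ((az - cx) / spec.rf_width_deg) ** 2)
    wy = np.exp(-0.5 * ((el - cy) / spec.rf_width_deg) ** 2)
    w = wy[:, None] * wx[None, :]
    w /= w.sum()
    return np.tensordot(movie.frames, w, axes=([1, 2], [0, 1]))


def _temporal_filter(lum: np.ndarray, spec: InputClassSpec, fs_hz: float) -> np.ndarray:
    """Latency-shifted difference-of-exponentials filtering, unit DC gain."""
    dt = 1.0 / fs_hz
    r, d = (tc * 1e-3 for tc in spec.kernel_time_constants_ms)
    t = np.arange(0.0, 6.0 * d, dt)
    k = np.exp(-t / d) - np.exp(-t / r)
    k /= k.sum()                            # unit response to a sustained step
    drive = np.convolve(lum, k)[: lum.size]
    return pm.shift_trace(drive, spec.latency_ms * 1e-3, fs_hz)


def _upsample_hold(x: np.ndarray, from_hz: float, to_hz: float) -> np.ndarray:
    n_out = int(round(x.size * to_hz / from_hz))
    idx = np.minimum((np.arange(n_out) * from_hz / to_hz).astype(int), x.size - 1)
    return x[idx]


def synth_presyn_response(
    spec: InputClassSpec,
    movie: StimulusMovie,
    seed: int | np.random.Generator = 0,
    fs_hz: float = 1000.0,
    noise_sd_mV: float | None = None,
) -> VoltageTrace:
    """Synthetic membrane voltage (mV) of one input class at 1 kHz.

    ``trace = tonic + sign * amplitude * filtered local luminance + noise``;
    ON-hyperpolarizing Mi9 therefore rests depolarized in darkness and
    dips below its tonic level when its receptive field brightens.
    """
    rng = np.random.default_rng(seed)
    lum = _upsample_hold(_local_luminance(movie, spec), movie.frame_rate, fs_hz)
    drive = _temporal_filter(lum, spec, fs_hz)
    sd = spec.noise_sd_mV if noise_sd_mV is None else noise_sd_mV
    v = spec.tonic_level_mV + spec.sign * spec.amplitude_mV * drive
    if sd > 0:
        v = v + rng.normal(0.0, sd, size=v.size)
    return VoltageTrace(v, fs_hz, stimulus_id=f"presyn:{spec.class_name}")


def presyn_v_norm(
    gt: GroundTruth,
    movie: StimulusMovie,
    fs_hz: float = 1000.0,
    noise_sd_mV: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Noiseless-by-default normalized presynaptic drives in [0, 1].

    Uses each class's nominal voltage range (not the per-trace min/max),
    so the mapping is well defined even for stimuli that never excite a
    class — e.g. darkness, where Mi9 sits at 1 and the rest at 0.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for cls, spec in gt.input_specs.items():
        tr = synth_presyn_response(spec, movie, rng, fs_hz, noise_sd_mV)
        lo, hi = spec.v_range_mv
        out[cls] = np.clip((tr.v_mv - lo) / (hi - lo), 0.0, 1.0)
    return out


def synth_t4_vm(
    gt: GroundTruth,
    movie: StimulusMovie,
    fs_hz: float = 1000.0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Noise-free T4 voltage (mV) and the conductances that produced it."""
    v_norm = presyn_v_norm(gt, movie, fs_hz)
    g = pm.conductances(v_norm, gt.synaptic_params)
    return pm.simulate_vm(g, gt.synaptic_params), g


def synth_t4_episode_set(
    gt: GroundTruth,
    movie: StimulusMovie,
    holding_currents_pA=(-5.0, 0.0),
    baseline_Rin_GOhm: float = BASELINE_RIN_GOHM,
    noise_sd_mV: float = 0.5,
    seed: int | np.random.Generator = 0,
    fs_hz: float = 1000.0,
) -> EpisodeSet:
    """Current-clamp episodes of one T4 cell at varying holding currents.

    Each sweep is the forward model response plus ``I_hold * R_in(t)``,
    where the input-resistance trace follows the model's total relative
    conductance, scaled so its dark-state (first-sample) value equals
    ``baseline_Rin_GOhm``, plus white voltage noise.
    """
    holding = list(holding_currents_pA)
    if not holding:
        raise ValueError("need at least one holding current")
    if any(not (-10.0 <= h <= 0.0) for h in holding):
        raise ValueError("holding currents must lie in [-10, 0] pA")
    rng = np.random.default_rng(seed)
    vm, g = synth_t4_vm(gt, movie, fs_hz)
    g_tot = pm.total_conductance(g, gt.synaptic_params)
    rin = baseline_Rin_GOhm * g_tot[0] / g_tot
    sweeps = []
    for h in holding:
        v = vm + h * rin
        if noise_sd_mV > 0:
            v = v + rng.normal(0.0, noise_sd_mV, size=v.size)
        sweeps.append(VoltageTrace(v, fs_hz, holding_pa=h, stimulus_id="episode"))
    return EpisodeSet(sweeps, meta={"baseline_rin_gohm": baseline_Rin_GOhm,
                                    "rin_gohm": rin})


FIT_CONDITIONS = ("ON-PD", "ON-ND", "OFF-PD", "OFF-ND")


def synth_fit_dataset(
    gt: GroundTruth,
    noise_sd_mV: float = 1.0,
    seed: int | np.random.Generator = 0,
    fs_hz: float = 1000.0,
    extent: tuple[float, float, float, float] = (0.0, 56.0, 0.0, 56.0),
    pad_s: float = 0.3,
) -> tuple[dict[str, dict[str, np.ndarray]], dict[str, np.ndarray]]:
    """The four-condition fitting dataset: ON/OFF edges in PD and ND.

    Presynaptic voltages are synthesized noise-free for each condition,
    min-max normalized jointly across the four conditions (ratios
    retained), and the T4 target trace is the forward model on those
    normalized drives under ``gt.synaptic_params`` plus white noise.
    Returns ``(v_norm[cond][class], data[cond])`` ready for
    :mod:`t4circuit.inference`.
    """
    from .stimuli import EdgeSpec, make_edge

    rng = np.random.default_rng(seed)
    pd_deg = 0.0
    movies = {
        "ON-PD": make_edge(EdgeSpec("ON", pd_deg, 30.0, extent, pad_s)),
        "ON-ND": make_edge(EdgeSpec("ON", pd_deg + 180.0, 30.0, extent, pad_s)),
        "OFF-PD": make_edge(EdgeSpec("OFF", pd_deg, 30.0, extent, pad_s)),
        "OFF-ND": make_edge(EdgeSpec("OFF", pd_deg + 180.0, 30.0, extent, pad_s)),
    }
    raw = {cls: {} for cls in gt.input_specs}
    for cond, movie in movies.items():
        for cls, spec in gt.input_specs.items():
            raw[cls][cond] = synth_presyn_response(
                spec, movie, rng, fs_hz, noise_sd_mV=0.0).v_mv
    normed = pm.normalize_inputs(raw)
    v_norm = {cond: {cls: normed[cls][cond] for cls in normed}
              for cond in movies}
    data = {}
    for cond in movies:
        g = pm.conductances(v_norm[cond], gt.synaptic_params)
        v = pm.simulate_vm(g, gt.synaptic_params)
        if noise_sd_mV > 0:
            v = v + rng.normal(0.0, noise_sd_mV, size=v.size)
        data[cond] = v
    return v_norm, data


def synth_population(
    n_cells: int,
    rf_scatter_deg: float,
    pd_distribution,
    gt: GroundTruth,
    movie: StimulusMovie,
    seed: int | np.random.Generator = 0,
    fs_hz: float = 1000.0,
    noise_sd_mV: float = 0.0,
) -> list[dict]:
    """A population of T4 cells sharing one ground truth.

    Receptive-field centres are jittered by an isotropic Gaussian of
    s.d. ``rf_scatter_deg``; preferred directions are drawn from
    ``pd_distribution`` (a sequence cycled over cells, or a callable
    ``rng -> deg``).  Each record carries the cell's voltage response to
    ``movie`` together with the true centre and PD so that alignment and
    averaging operations can be scored against the generator.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    base_center = np.array(gt.input_specs["Mi1"].rf_center_deg)
    cells = []
    for k in range(n_cells):
        if callable(pd_distribution):
            pd_deg = float(pd_distribution(rng))
        else:
            pd_deg = float(np.asarray(pd_distribution).ravel()[
                k % np.asarray(pd_distribution).size])
        jitter = rng.normal(0.0, rf_scatter_deg, size=2) if rf_scatter_deg > 0 \
            else np.zeros(2)
        center = tuple(base_center + jitter)
        specs = default_input_specs(pd_deg=pd_deg, center_deg=center,
                                    noise_sd_mV=0.0)
        cell_gt = GroundTruth(gt.synaptic_params, specs, gt.seed)
        vm, _ = synth_t4_vm(cell_gt, movie, fs_hz)
        if noise_sd_mV > 0:
            vm = vm + rng.normal(0.0, noise_sd_mV, size=vm.size)
        cells.append({
            "vm": VoltageTrace(vm, fs_hz, stimulus_id=f"cell{k}"),
            "true_center_deg": center,
            "true_pd_deg": pd_deg,
        })
    return cells
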