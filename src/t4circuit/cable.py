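"""Passive multi-compartment cable model on an SWC morphology.

The morphology is a tree of cylindrical compartments (one per SWC sample
point; a compartment's cable runs from its parent's position to its own).
Uniform passive parameters (axial resistivity R_a, specific membrane
resistance R_m and capacitance C_m) define a sparse symmetric conductance
matrix ``M``.  Voltages obey the implicit (backward-Euler) update

    M_dyn V(t) = V(t-1) * c_m / dt + E_leak * g_leak + I(t)

with ``M_dyn = M + diag(c_m / dt)``; the steady state drops the
capacitive terms.  Synapses enter as a conductance on the diagonal and
``g_syn * E_syn`` on the right-hand side.  A proportional-integral
controller emulates a voltage-clamp amplifier at a chosen compartment.

Units are SI internally (V, A, S, F, m); interfaces use mV, pA, GΩ and
µm, which is what electrophysiologists read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "Morphology",
    "CableParams",
    "CableSystem",
    "ClampConfig",
    "Synapse",
    "read_swc",
    "assemble",
    "solve_steady",
    "step_dynamic",
    "run_voltage_clamp",
    "iv_reversal",
    "transfer_attenuation",
]

_UM = 1e-6  # metres per micrometre


class SWCError(ValueError):
    """Raised for malformed SWC input (dangling parents, cycles, bad radii)."""


@dataclass
class Morphology:
    """Compartment tree.

    Arrays are indexed by compartment (0 = root).  ``parent`` holds the
    parent index, -1 for the root.  ``length_um`` is the cable length of
    the compartment (distance to the parent point for SWC input; the
    root's length may be set explicitly for synthetic morphologies and is
    0 when read from SWC).  ``diameter_um`` > 0 everywhere.
    """

    parent: np.ndarray
    length_um: np.ndarray
    diameter_um: np.ndarray
    xyz_um: np.ndarray | None = None
    region: np.ndarray | None = None
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.length_um = np.asarray(self.length_um, dtype=float)
        self.diameter_um = np.asarray(self.diameter_um, dtype=float)
        n = self.parent.size
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise SWCError(f"expected exactly one root, found {roots.size}")
        if np.any(self.diameter_um <= 0):
            raise SWCError("diameters must be positive")
        if np.any(self.length_um < 0):
            raise SWCError("lengths must be non-negative")
        nonroot = np.flatnonzero(self.parent >= 0)
        if np.any(self.length_um[nonroot] <= 0):
            raise SWCError("zero-length edge")
        # verify the parent map is a tree (acyclic, ancestors resolve to root)
        depth = np.full(n, -1, dtype=int)
        depth[roots[0]] = 0
        for i in range(n):
            chain = []
            j = i
            while depth[j] < 0:
                chain.append(j)
                j = self.parent[j]
                if len(chain) > n:
                    raise SWCError("cycle in parent references")
            for k, node in enumerate(reversed(chain)):
                depth[node] = depth[j] + k + 1

    @property
    def n_compartments(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def path_length_um(self, i: int) -> float:
        """Cable distance from compartment ``i`` to the root."""
        d = 0.0
        while self.parent[i] >= 0:
            d += self.length_um[i]
            i = self.parent[i]
        return d


@dataclass
class CableParams:
    """Uniform passive membrane parameters."""

    r_a_ohm_cm: float = 150.0       # axial resistivity
    r_m_kohm_cm2: float = 28.0      # specific membrane resistance
    c_m_uf_cm2: float = 1.0         # specific membrane capacitance
    e_leak_mv: float = -65.0

    def __post_init__(self) -> None:
        if min(self.r_a_ohm_cm, self.r_m_kohm_cm2, self.c_m_uf_cm2) <= 0:
            raise ValueError("R_a, R_m and C_m must be positive")
        if not np.isfinite(self.e_leak_mv):
            raise ValueError("E_leak must be finite")

    # SI conversions
    @property
    def r_a_si(self) -> float:          # Ω·m
        return self.r_a_ohm_cm * 1e-2

    @property
    def r_m_si(self) -> float:          # Ω·m²
        return self.r_m_kohm_cm2 * 1e3 * 1e-4

    @property
    def c_m_si(self) -> float:          # F/m²
        return self.c_m_uf_cm2 * 1e-6 * 1e4

    @property
    def tau_m_s(self) -> float:
        """Membrane time constant R_m C_m in seconds."""
        return self.r_m_si * self.c_m_si


@dataclass
class Synapse:
    """A conductance at one compartment: ``g_ns`` nanosiemens, ``e_mv`` reversal."""

    site: int
    g_ns: float
    e_mv: float


class CableSystem:
    """Assembled conductance/capacitance system for one morphology."""

    def __init__(
        self,
        m_steady: sparse.csr_matrix,
        g_leak: np.ndarray,
        c_m: np.ndarray,
        params: CableParams,
        morph: Morphology,
    ):
        self.m_steady = m_steady      # S; diag = g_leak + axial sums
        self.g_leak = g_leak          # S per compartment
        self.c_m = c_m                # F per compartment
        self.params = params
        self.morph = morph

    @property
    def n(self) -> int:
        return self.g_leak.size

    def rest_v(self) -> np.ndarray:
        return np.full(self.n, self.params.e_leak_mv * 1e-3)


def read_swc(source) -> Morphology:
    """Parse an SWC morphology (7 whitespace-separated columns, '#' comments).

    One compartment is created per sample point.  Length is the Euclidean
    distance to the parent point (root: 0); diameter is twice the radius
    column.  Dangling parent references, non-positive radii and cycles
    raise :class:`SWCError` naming the offending line.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    ids, types, xyz, radii, parents, lines = [], [], [], [], [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCError(f"line {lineno}: expected 7 columns, got {len(cols)}")
        try:
            ids.append(int(cols[0]))
            types.append(int(cols[1]))
            xyz.append([float(c) for c in cols[2:5]])
            radii.append(float(cols[5]))
            parents.append(int(cols[6]))
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}") from exc
        lines.append(lineno)
        if radii[-1] <= 0:
            raise SWCError(f"line {lineno}: non-positive radius {radii[-1]}")
    if not ids:
        raise SWCError("empty SWC file")
    index = {sid: i for i, sid in enumerate(ids)}
    parent_idx = np.empty(len(ids), dtype=int)
    for i, (pid, lineno) in enumerate(zip(parents, lines)):
        if pid == -1:
            parent_idx[i] = -1
        elif pid in index:
            parent_idx[i] = index[pid]
        else:
            raise SWCError(f"line {lineno}: unknown parent id {pid}")
    xyz = np.asarray(xyz, dtype=float)
    length = np.zeros(len(ids))
    for i, p in enumerate(parent_idx):
        if p >= 0:
            length[i] = float(np.linalg.norm(xyz[i] - xyz[p]))
    return Morphology(
        parent=parent_idx,
        length_um=length,
        diameter_um=2.0 * np.asarray(radii, dtype=float),
        xyz_um=xyz,
        region=np.asarray(types, dtype=int),
        ids=np.asarray(ids, dtype=int),
    )


def assemble(morph: Morphology, params: CableParams) -> CableSystem:
    """Build the sparse conductance matrix and membrane vectors.

    Per compartment (cylinder of length L, diameter d, both from the
    child point): membrane leak ``g_m = pi d L / R_m`` and capacitance
    ``c = C_m pi d L``; per edge to the parent, axial conductance
    ``g_ax = (pi d^2 / 4) / (R_a L)``.  The root contributes membrane
    terms through its own (possibly zero) length.
    """
    n = morph.n_compartments
    L = morph.length_um * _UM
    d = morph.diameter_um * _UM
    area = np.pi * d * L
    g_m = area / params.r_m_si
    c_m = area * params.c_m_si

    rows, cols, vals = [], [], []
    diag = g_m.copy()
    for i in range(n):
        p = morph.parent[i]
        if p < 0:
            continue
        if L[i] <= 0:
            raise ValueError(f"zero-length edge at compartment {i}")
        g_ax = (np.pi * d[i] ** 2 / 4.0) / (params.r_a_si * L[i])
        rows += [i, p]
        cols += [p, i]
        vals += [-g_ax, -g_ax]
        diag[i] += g_ax
        diag[p] += g_ax
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    m = sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
    return CableSystem(m, g_m, c_m, params, morph)


def _rhs(system: CableSystem, injections_pa: dict[int, float] | None,
         synapses: list[Synapse] | None):
    """Right-hand side E_leak*g_leak + I + sum g_syn E_syn, plus diagonal additions."""
    b = system.params.e_leak_mv * 1e-3 * system.g_leak.copy()
    extra_diag = np.zeros(system.n)
    if injections_pa:
        for site, i_pa in injections_pa.items():
            b[site] += i_pa * 1e-12
    if synapses:
        for syn in synapses:
            g = syn.g_ns * 1e-9
            extra_diag[syn.site] += g
            b[syn.site] += g * syn.e_mv * 1e-3
    return b, extra_diag


def _with_diag(m: sparse.csr_matrix, extra: np.ndarray) -> sparse.csr_matrix:
    if not np.any(extra):
        return m
    return m + sparse.diags(extra)


def solve_steady(
    system: CableSystem,
    injections_pa: dict[int, float] | None = None,
    synapses: list[Synapse] | None = None,
) -> np.ndarray:
    """Steady-state membrane potential per compartment, in mV."""
    b, extra = _rhs(system, injections_pa, synapses)
    v = spsolve(_with_diag(system.m_steady, extra).tocsc(), b)
    return v * 1e3


def step_dynamic(
    system: CableSystem,
    v_prev_mv: np.ndarray,
    injections_pa: dict[int, float] | None = None,
    synapses: list[Synapse] | None = None,
    dt_ms: float = 0.1,
) -> np.ndarray:
    """One implicit-Euler step of length ``dt_ms``; returns V in mV.

    Unconditionally stable; with time-invariant inputs the iteration
    converges to the ``solve_steady`` fixed point.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    dt = dt_ms * 1e-3
    b, extra = _rhs(system, injections_pa, synapses)
    cap = system.c_m / dt
    b = b + cap * np.asarray(v_prev_mv, float) * 1e-3
    m = _with_diag(system.m_steady, extra) + sparse.diags(cap)
    return spsolve(m.tocsc(), b) * 1e3


@dataclass
class ClampConfig:
    """Voltage-clamp emulation settings.

    ``k_p`` is the proportional gain in siemens, ``k_i`` the dimensionless
    integral gain on the previous injected current.  With ``k_i = 1`` the
    controller has pure integral action and holds the clamped compartment
    at ``v_cmd`` exactly at steady state.
    """

    site: int = 0
    k_p: float = 2e9
    k_i: float = 1.0
    v_cmd_mv: float | np.ndarray = -65.0

    def __post_init__(self) -> None:
        if self.k_p <= 0:
            raise ValueError("K_p must be positive")
        if not (0.0 <= self.k_i <= 1.0):
            raise ValueError("K_i must lie in [0, 1]")


def run_voltage_clamp(
    system: CableSystem,
    clamp: ClampConfig,
    synapse_schedule=None,
    n_steps: int = 2000,
    dt_ms: float = 0.1,
    v_init_mv: np.ndarray | None = None,
    i_overflow_pa: float = 1e9,
):
    """Clamp one compartment with a PI controller while stepping the cable.

    ``synapse_schedule`` maps a step index to a list of :class:`Synapse`
    (or is a callable ``step -> list``).  The injected current obeys

        I(t) = K_p (V_cmd(t) - V_site(t)) + K_i I(t-1)

    evaluated implicitly within the backward-Euler step (K_p enters the
    matrix diagonal), so arbitrarily stiff gains remain stable.  Returns
    ``(i_pa, v_mv)``: the injected-current trace (pA) and the voltage of
    every compartment over time (mV).
    """
    if not (0 <= clamp.site < system.n):
        raise ValueError("clamp site outside morphology")
    dt = dt_ms * 1e-3
    v = (system.rest_v() if v_init_mv is None else np.asarray(v_init_mv, float) * 1e-3)
    vc = np.asarray(clamp.v_cmd_mv, dtype=float)
    v_cmd = np.full(n_steps, float(vc)) if vc.ndim == 0 else np.broadcast_to(vc, (n_steps,))
    cap = system.c_m / dt
    i_prev = 0.0
    i_out = np.empty(n_steps)
    v_out = np.empty((n_steps, system.n))
    lu_cache: dict[bytes, object] = {}
    for step in range(n_steps):
        if callable(synapse_schedule):
            syns = synapse_schedule(step)
        elif synapse_schedule:
            syns = synapse_schedule.get(step, [])
        else:
            syns = []
        b, extra = _rhs(system, None, syns)
        b = b + cap * v
        # implicit clamp: K_p on the diagonal, K_p V_cmd + K_i I_prev on the RHS
        extra_clamped = extra.copy()
        extra_clamped[clamp.site] += clamp.k_p
        b_clamped = b.copy()
        b_clamped[clamp.site] += clamp.k_p * v_cmd[step] * 1e-3 + clamp.k_i * i_prev
        key = extra_clamped.tobytes()
        lu = lu_cache.get(key)
        if lu is None:
            m = _with_diag(system.m_steady, extra_clamped) + sparse.diags(cap)
            lu = sparse.linalg.splu(m.tocsc())
            lu_cache[key] = lu
        v = lu.solve(b_clamped)
        # injected current from the node balance of the unclamped system;
        # algebraically K_p (V_cmd - V_site) + K_i I_prev, but numerically
        # stable for stiff K_p where that difference underflows
        fkey = b"free" + extra.tobytes()
        m_free = lu_cache.get(fkey)
        if m_free is None:
            m_free = _with_diag(system.m_steady, extra) + sparse.diags(cap)
            lu_cache[fkey] = m_free
        i_prev = float((m_free @ v - b)[clamp.site])
        if abs(i_prev) > i_overflow_pa * 1e-12:
            raise RuntimeError(
                "voltage-clamp controller diverged; reduce K_p or K_i")
        i_out[step] = i_prev * 1e12
        v_out[step] = v * 1e3
    return i_out, v_out


def iv_reversal(
    system: CableSystem,
    clamp_site: int,
    v_cmd_list_mv,
    synapse_site: int,
    g_syn_ns: float,
    e_syn_mv: float,
    settle_steps: int = 3000,
    event_steps: int = 1500,
    dt_ms: float = 0.1,
    k_p: float = 2e9,
    k_i: float = 1.0,
):
    """Estimate a synaptic reversal potential from clamp I-V sweeps.

    For each command voltage the clamp settles, a synaptic conductance
    step is applied at ``synapse_site``, and the evoked (baseline-
    subtracted, i.e. leak-subtracted) peak current is measured.  A linear
    regression of evoked current on command voltage yields the
    zero-crossing, returned as the reversal estimate in mV together with
    the per-sweep evoked currents.  If the evoked currents do not change
    sign across the sweeps the estimate is an extrapolation and
    ``bracketed`` is False.
    """
    v_cmds = np.asarray(v_cmd_list_mv, dtype=float)
    if v_cmds.size < 3:
        raise ValueError("need at least 3 command voltages")
    peaks = np.empty(v_cmds.size)
    syn = Synapse(synapse_site, g_syn_ns, e_syn_mv)
    for k, vc in enumerate(v_cmds):
        cfg = ClampConfig(site=clamp_site, k_p=k_p, k_i=k_i, v_cmd_mv=vc)
        schedule = lambda s: [syn] if s >= settle_steps else []
        i_tr, _ = run_voltage_clamp(system, cfg, schedule,
                                    n_steps=settle_steps + event_steps,
                                    dt_ms=dt_ms)
        baseline = np.mean(i_tr[settle_steps - 200:settle_steps])
        evoked = i_tr[settle_steps:] - baseline
        peaks[k] = evoked[np.argmax(np.abs(evoked))]
    slope, intercept = np.polyfit(v_cmds, peaks, 1)
    e_rev = -intercept / slope
    bracketed = bool(np.min(peaks) < 0 < np.max(peaks))
    return {"e_rev_mv": float(e_rev), "evoked_pa": peaks,
            "v_cmd_mv": v_cmds, "bracketed": bracketed}


def transfer_attenuation(system: CableSystem, source: int, target: int,
                         i_pa: float = 1.0) -> float:
    """Steady-state voltage attenuation dV_target / dV_source.

    A small current injected at ``source`` perturbs the resting state;
    the ratio lies in (0, 1] for a passive tree and equals 1 when
    ``source == target``.
    """
    for c in (source, target):
        if not (0 <= c < system.n):
            raise ValueError(f"compartment {c} outside morphology")
    v0 = solve_steady(system)
    v1 = solve_steady(system, injections_pa={source: i_pa})
    dv = v1 - v0
    return float(dv[target] / dv[source])
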