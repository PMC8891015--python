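"""Parameter estimation and likelihood-free uncertainty for the point model.

Twelve free parameters (five gains, five thresholds, E_leak, g_leak) are
estimated by bounded least squares against T4 voltage traces across
stimulus conditions, with multi-start local optimization.  Uncertainty
is quantified by rejection sampling: parameter sets drawn uniformly
within the fitting bounds are simulated, ranked by root-mean-square
voltage error against the data, and the best fraction kept as posterior
samples.  Because scaling all conductances (gains and g_leak) by a
common factor leaves the model output exactly unchanged, only ratios to
g_leak are identifiable; results therefore also report gains relative
to the leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from . import point_model as pm

__all__ = [
    "FitSpec",
    "PosteriorSamples",
    "params_to_vector",
    "vector_to_params",
    "simulate_conditions",
    "loss",
    "fit",
    "posterior",
    "identifiable_summary",
]

#: vector layout: 5 gains, 5 thresholds, e_leak, g_leak
PARAM_NAMES = (
    [f"gain_{c}" for c in pm.CLASSES]
    + [f"thld_{c}" for c in pm.CLASSES]
    + ["e_leak", "g_leak"]
)

_G_EPS = 1e-6  # keep g_leak strictly positive inside the printed [0, 3] bound


def default_bounds() -> list[tuple[float, float]]:
    """Fitting bounds: gains [0, 2], thresholds [0, 1], E_leak [-80, -45] mV,
    g_leak [0, 3]."""
    return ([(0.0, 2.0)] * 5 + [(0.0, 1.0)] * 5
            + [(-80.0, -45.0)] + [(_G_EPS, 3.0)])


@dataclass
class FitSpec:
    """Configuration of the bounded least-squares fit."""

    bounds: list[tuple[float, float]] = field(default_factory=default_bounds)
    n_starts: int = 8
    max_iter: int = 400
    seed: int = 0
    transfer_form: str = "relu"
    initializer: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.bounds) != 12:
            raise ValueError("expected 12 parameter bounds")


def params_to_vector(p: pm.SynapticParams) -> np.ndarray:
    return np.array(
        [p.gains[c] for c in pm.CLASSES]
        + [p.thresholds[c] for c in pm.CLASSES]
        + [p.e_leak, p.g_leak]
    )


def vector_to_params(x: np.ndarray) -> pm.SynapticParams:
    x = np.asarray(x, dtype=float)
    return pm.SynapticParams(
        gains={c: float(x[i]) for i, c in enumerate(pm.CLASSES)},
        thresholds={c: float(x[5 + i]) for i, c in enumerate(pm.CLASSES)},
        e_leak=float(x[10]),
        g_leak=max(float(x[11]), _G_EPS),
    )


def simulate_conditions(
    params: pm.SynapticParams,
    v_norm: dict[str, dict[str, np.ndarray]],
    form: str = "relu",
) -> dict[str, np.ndarray]:
    """Forward model per stimulus condition.

    ``v_norm[condition][class]`` holds normalized presynaptic drives.
    """
    out = {}
    for cond, traces in v_norm.items():
        g = pm.conductances(traces, params, form=form)
        out[cond] = pm.simulate_vm(g, params)
    return out


def loss(
    params: pm.SynapticParams,
    v_norm: dict[str, dict[str, np.ndarray]],
    data: dict[str, np.ndarray],
    form: str = "relu",
) -> float:
    """Sum of squared voltage residuals over all conditions and samples."""
    total = 0.0
    for cond, d in data.items():
        g = pm.conductances(v_norm[cond], params, form=form)
        v = pm.simulate_vm(g, params)
        d = np.asarray(d, dtype=float)
        if v.shape != d.shape:
            raise ValueError(f"condition {cond!r}: model/data length mismatch")
        total += float(np.sum((v - d) ** 2))
    return total


def _loss_vec(x, v_norm, data, form):
    return loss(vector_to_params(x), v_norm, data, form=form)


def fit(
    spec: FitSpec,
    v_norm: dict[str, dict[str, np.ndarray]],
    data: dict[str, np.ndarray],
) -> tuple[pm.SynapticParams, float, dict]:
    """Multi-start bounded minimization of the squared-error loss.

    Starting points are the (optional) initializer plus Latin-hypercube
    draws over the bounds; the best converged solution is returned as
    ``(params, loss, info)``.  The reported loss is never higher than
    the loss at the initializer (the initializer itself is a candidate).
    """
    if not data:
        raise ValueError("need at least one stimulus condition")
    rng = np.random.default_rng(spec.seed)
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    starts = []
    if spec.initializer is not None:
        starts.append(np.clip(np.asarray(spec.initializer, float), lo, hi))
    n_lhs = max(spec.n_starts - len(starts), 0)
    if n_lhs:
        sampler = qmc.LatinHypercube(d=12, seed=rng)
        starts += list(lo + sampler.random(n_lhs) * (hi - lo))

    best_x, best_loss, n_ok = None, np.inf, 0
    for x0 in starts:
        res = optimize.minimize(
            _loss_vec, x0, args=(v_norm, data, spec.transfer_form),
            method="L-BFGS-B", bounds=spec.bounds,
            options={"maxiter": spec.max_iter},
        )
        if np.isfinite(res.fun):
            n_ok += 1
            for cand_x, cand_f in ((res.x, res.fun),
                                   (x0, _loss_vec(x0, v_norm, data,
                                                  spec.transfer_form))):
                if cand_f < best_loss:
                    best_x, best_loss = np.asarray(cand_x), float(cand_f)
    if best_x is None:
        raise RuntimeError(f"all {len(starts)} starts failed to converge")
    info = {"n_starts": len(starts), "n_converged": n_ok}
    return vector_to_params(best_x), best_loss, info


@dataclass
class PosteriorSamples:
    """Accepted rejection-sampling draws, ranked by distance to the data."""

    samples: np.ndarray      # (n_keep, 12), within prior bounds
    distances: np.ndarray    # ascending RMS voltage error, mV
    bounds: list[tuple[float, float]]
    n_sim: int

    def marginal(self, name: str) -> np.ndarray:
        return self.samples[:, PARAM_NAMES.index(name)]

    def central_interval(self, name: str, mass: float = 0.95) -> tuple[float, float]:
        m = self.marginal(name)
        a = (1.0 - mass) / 2.0
        return tuple(np.quantile(m, [a, 1.0 - a]))


def posterior(
    spec: FitSpec,
    v_norm: dict[str, dict[str, np.ndarray]],
    data: dict[str, np.ndarray],
    n_sim: int = 20000,
    n_keep: int = 10000,
    seed: int = 0,
) -> PosteriorSamples:
    """Rejection-sampling posterior over the 12 model parameters.

    ``n_sim`` parameter sets are drawn uniformly within the bounds; each
    is simulated and scored by the RMS voltage error concatenated over
    conditions; the ``n_keep`` closest are returned with uniform
    weights, distances sorted ascending.
    """
    if n_keep > n_sim:
        raise ValueError("n_keep must not exceed n_sim")
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    draws = lo + rng.random((n_sim, 12)) * (hi - lo)
    n_total = sum(np.asarray(d).size for d in data.values())
    dist = np.empty(n_sim)
    for k in range(n_sim):
        sse = loss(vector_to_params(draws[k]), v_norm, data,
                   form=spec.transfer_form)
        dist[k] = np.sqrt(sse / n_total)
    order = np.argsort(dist, kind="stable")[:n_keep]
    return PosteriorSamples(draws[order], dist[order], list(spec.bounds), n_sim)


def identifiable_summary(p: pm.SynapticParams) -> dict[str, float]:
    """The scale-invariant parameter combinations the data constrain:
    gains relative to g_leak, thresholds, and E_leak."""
    out = {f"gain_{c}/g_leak": p.gains[c] / p.g_leak for c in pm.CLASSES}
    out.update({f"thld_{c}": p.thresholds[c] for c in pm.CLASSES})
    out["e_leak"] = p.e_leak
    return out
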