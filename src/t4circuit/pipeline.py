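"""End-to-end orchestration: synth -> rf -> simulate -> fit -> posterior -> report.

A single YAML/dict config drives the whole analysis with one global
seed.  Stages always execute in the fixed order above (each may be
omitted); the global seed is expanded per stage through a counter-based
``SeedSequence`` scheme so any stage can be reproduced in isolation.
Every run writes a JSON manifest recording the config hash, the
per-stage seeds and the SHA-256 of each artifact together with the
hashes of the artifacts it consumed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import inference, point_model as pm, rf as rf_mod, synth
from .stimuli import make_white_noise

__all__ = ["STAGE_ORDER", "PipelineError", "validate_config", "run"]

STAGE_ORDER = ("synth", "rf", "simulate", "fit", "posterior", "report")

log = logging.getLogger("t4circuit.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _config_hash(config: dict) -> str:
    # output location does not affect the science; exclude it so reruns
    # into different directories remain byte-identical
    payload = {k: v for k, v in config.items() if k != "out_dir"}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seed(global_seed: int, stage: str) -> int:
    counter = STAGE_ORDER.index(stage)
    ss = np.random.SeedSequence([int(global_seed), counter])
    return int(ss.generate_state(1)[0] % (2**31))


def validate_config(config: dict) -> dict:
    """Check schema and path resolvability before any stage runs."""
    if not isinstance(config, dict):
        raise PipelineError("config", "config must be a mapping")
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    cfg.setdefault("out_dir", "t4_run")
    stages = cfg.get("stages", {})
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError("config", f"unknown stages: {sorted(unknown)}")
    for name, block in stages.items():
        if block is None:
            stages[name] = {}
        elif not isinstance(block, dict):
            raise PipelineError(name, "stage block must be a mapping")
        for key in ("input", "params_file"):
            p = stages.get(name, {}).get(key)
            if p is not None and not Path(p).exists():
                raise PipelineError(name, f"referenced file not found: {p}")
    cfg["stages"] = stages
    return cfg


def run(config: dict | str | Path) -> dict:
    """Execute the configured stages; returns the manifest (also written).

    Deterministic stages are byte-identical across reruns of the same
    config, because all randomness derives from the per-stage seeds.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = validate_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    manifest = {"config_hash": chash, "seed": cfg["seed"], "artifacts": {}}
    state: dict = {"gt": synth.default_ground_truth()}

    def record(name: str, path: Path, inputs: list[str]):
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": _file_hash(path),
            "inputs": {k: manifest["artifacts"][k]["sha256"] for k in inputs},
        }

    for stage in STAGE_ORDER:
        if stage not in cfg["stages"]:
            continue
        block = cfg["stages"][stage]
        seed = _stage_seed(cfg["seed"], stage)
        log.info("running stage %s (seed %d)", stage, seed)
        try:
            if stage == "synth":
                v_norm, data = synth.synth_fit_dataset(
                    state["gt"], noise_sd_mV=block.get("noise_sd_mV", 1.0),
                    seed=seed)
                state["v_norm"], state["data"] = v_norm, data
                path = out_dir / "dataset.h5"
                with h5py.File(path, "w") as h5:
                    h5.attrs["config_hash"] = chash
                    h5.attrs["seed"] = seed
                    for cond in data:
                        grp = h5.create_group(cond)
                        grp.create_dataset("t4_vm_mv", data=data[cond])
                        for cls, tr in v_norm[cond].items():
                            grp.create_dataset(f"v_norm/{cls}", data=tr)
                record("dataset", path, [])

            elif stage == "rf":
                seconds = block.get("duration_s", 120.0)
                movie = make_white_noise(
                    block.get("width_px", 12), block.get("height_px", 12),
                    seconds, seed=seed, origin=(16.8, 16.8))
                cells = synth.synth_population(
                    block.get("n_cells", 3), block.get("rf_scatter_deg", 2.0),
                    [0.0], state["gt"], movie, seed=seed)
                path = out_dir / "rf.h5"
                with h5py.File(path, "w") as h5:
                    h5.attrs["config_hash"] = chash
                    h5.attrs["seed"] = seed
                    for k, cell in enumerate(cells):
                        v = rf_mod.drift_correct(cell["vm"].v_mv, cell["vm"].fs_hz)
                        kern = rf_mod.reverse_correlate(
                            movie, v - v.mean(), vm_fs_hz=cell["vm"].fs_hz)
                        grp = h5.create_group(f"cell{k}")
                        grp.create_dataset("kernel", data=kern.kernel)
                        grp.create_dataset("lags_s", data=kern.lags_s)
                        grp.attrs["true_center_deg"] = cell["true_center_deg"]
                record("rf", path, ["dataset"] if "dataset" in
                       manifest["artifacts"] else [])

            elif stage == "simulate":
                if "v_norm" not in state:
                    raise PipelineError(stage, "requires the synth stage")
                sims = inference.simulate_conditions(
                    state["gt"].synaptic_params, state["v_norm"])
                path = out_dir / "simulation.h5"
                with h5py.File(path, "w") as h5:
                    h5.attrs["config_hash"] = chash
                    for cond, v in sims.items():
                        h5.create_dataset(cond, data=v)
                record("simulation", path, ["dataset"])

            elif stage == "fit":
                if "data" not in state:
                    raise PipelineError(stage, "requires the synth stage")
                spec = inference.FitSpec(
                    n_starts=block.get("n_starts", 4), seed=seed,
                    initializer=inference.params_to_vector(
                        state["gt"].synaptic_params) if block.get(
                            "init_at_truth", False) else None)
                params, final_loss, info = inference.fit(
                    spec, state["v_norm"], state["data"])
                state["fit"] = params
                path = out_dir / "fit.json"
                path.write_text(json.dumps({
                    "params": params.to_dict(), "loss": final_loss,
                    "identifiable": inference.identifiable_summary(params),
                    **info}, indent=2))
                record("fit", path, ["dataset"])

            elif stage == "posterior":
                if "data" not in state:
                    raise PipelineError(stage, "requires the synth stage")
                post = inference.posterior(
                    inference.FitSpec(seed=seed), state["v_norm"],
                    state["data"], n_sim=block.get("n_sim", 2000),
                    n_keep=block.get("n_keep", 200), seed=seed)
                path = out_dir / "posterior.csv"
                header = ",".join(inference.PARAM_NAMES + ["distance_mv"])
                np.savetxt(path, np.column_stack([post.samples, post.distances]),
                           delimiter=",", header=header, comments="")
                state["posterior"] = post
                record("posterior", path, ["dataset"])

            elif stage == "report":
                rep = {"config_hash": chash, "seed": cfg["seed"]}
                if "fit" in state:
                    rep["fit_identifiable"] = inference.identifiable_summary(
                        state["fit"])
                if "posterior" in state:
                    rep["posterior_min_distance_mv"] = float(
                        state["posterior"].distances[0])
                path = out_dir / "report.json"
                path.write_text(json.dumps(rep, indent=2))
                record("report", path,
                       [k for k in ("fit", "posterior")
                        if k in manifest["artifacts"]])
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
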