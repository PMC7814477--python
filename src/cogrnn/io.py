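"""Run configuration, weight persistence, and deterministic fixtures.

Run configs are flat YAML/JSON documents with ``task``, ``network``,
``training`` and optional ``curriculum`` sections; unset keys are filled
from the documented defaults and the fully resolved config is echoed next
to the run outputs so a run can be reproduced from its artifacts alone.

Weight archives are single JSON documents holding every raw parameter,
every mask, the Dale signs and the network spec, with a format version tag.
JSON float serialization uses ``repr``, which round-trips IEEE doubles
exactly, so save -> load is lossless and the archive is diffable text.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import yaml

from .curriculum import CurriculumSpec, make_coherence_curriculum
from .network import (MaskSet, NetworkSpec, WeightSet, default_initializer,
                      init_alpha_identity, make_structured_masks)
from .task import Batch, Task
from .tasks import TASK_REGISTRY, make_task
from .training import LossSpec, TrainConfig

__all__ = [
    "RunConfig",
    "load_config",
    "resolve_config",
    "save_weights",
    "load_weights",
    "save_batch",
    "build_network",
    "FixtureSet",
    "make_fixture_set",
    "write_fixtures",
]

WEIGHT_FORMAT = "cogrnn-weights"
WEIGHT_VERSION = 1

_NETWORK_DEFAULTS = {
    "n_rec": 50, "dt": 10.0, "tau": 100.0, "sigma_rec": 0.05,
    "transfer": "relu", "dales_ratio": None,
    "initializer": "spectral_gaussian", "init_radius": 1.1,
    "init_alpha": 0.9, "masks": [],
}
_TRAINING_DEFAULTS = {
    "optimizer": "adam", "learning_rate": 1e-3, "n_iterations": 1000,
    "batch_size": 64, "eval_every": 10, "eval_batch": 128,
    "grad_clip_norm": None, "loss": "mean_squared_error",
    "lambda_l1_w": 0.0, "lambda_l2_w": 0.0, "lambda_l2_rate": 0.0,
}
_LOSS_KEYS = ("loss", "lambda_l1_w", "lambda_l2_w", "lambda_l2_rate")
_TOP_KEYS = ("task", "network", "training", "curriculum", "output_dir",
             "master_seed")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """A fully resolved run: built task, specs, and the resolved raw
    document (``resolved``) used for echoing and round-tripping."""

    task: Task
    task_name: str
    net_spec: NetworkSpec
    loss_spec: LossSpec
    train_cfg: TrainConfig
    curriculum: CurriculumSpec | None
    mask_recipes: list[dict]
    initializer: str
    init_radius: float
    init_alpha: float
    output_dir: str
    master_seed: int
    resolved: dict

    def echo(self, directory: str | None = None) -> str:
        """Write the resolved config as JSON; returns the path written."""
        directory = directory or self.output_dir
        os.makedirs(directory, exist_ok=True)
        path = os.path.join(directory, "resolved_config.json")
        with open(path, "w") as fh:
            json.dump(self.resolved, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def load_config(path: str) -> RunConfig:
    """Parse and resolve a YAML/JSON run config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return resolve_config(raw)


def _check_keys(section: dict, allowed, where: str):
    unknown = set(section) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config key(s): "
                         + ", ".join(f"{where}.{k}" for k in sorted(unknown)))


def resolve_config(raw: dict) -> RunConfig:
    """Fill defaults, validate keys and cross-section consistency, and build
    the task/spec objects."""
    _check_keys(raw, _TOP_KEYS, "<top>")
    if "task" not in raw:
        raise ValueError("config requires a 'task' section")

    # task ------------------------------------------------------------------
    task_sec = dict(raw["task"])
    name = task_sec.pop("name", None)
    if name not in TASK_REGISTRY:
        raise ValueError(f"task.name must be one of {sorted(TASK_REGISTRY)}, "
                         f"got {name!r}")
    cfg_cls = TASK_REGISTRY[name][1]
    _check_keys(task_sec, [f.name for f in dataclasses.fields(cfg_cls)], "task")
    task = make_task(name, **task_sec)

    # network ---------------------------------------------------------------
    net_sec = {**_NETWORK_DEFAULTS, **raw.get("network", {})}
    _check_keys(raw.get("network", {}),
                list(_NETWORK_DEFAULTS) + ["n_in", "n_out"], "network")
    for key, task_value in (("n_in", task.n_in), ("n_out", task.n_out)):
        if key in net_sec and net_sec[key] != task_value:
            raise ValueError(
                f"network.{key}={net_sec[key]} conflicts with task "
                f"'{name}' which requires {key}={task_value} "
                f"(task.{key} is derived from the task section)")
    if net_sec["initializer"] not in ("spectral_gaussian", "alpha_identity"):
        raise ValueError("network.initializer must be 'spectral_gaussian' "
                         "or 'alpha_identity'")
    dt_net = net_sec["dt"]
    if dt_net != task.dt:
        raise ValueError(f"network.dt={dt_net} conflicts with task.dt={task.dt}")
    net_spec = NetworkSpec(
        n_in=task.n_in, n_rec=net_sec["n_rec"], n_out=task.n_out,
        dt=net_sec["dt"], tau=net_sec["tau"], sigma_rec=net_sec["sigma_rec"],
        transfer=net_sec["transfer"], dales_ratio=net_sec["dales_ratio"])
    mask_recipes = list(net_sec["masks"])
    for recipe in mask_recipes:
        if "kind" not in recipe:
            raise ValueError("each network.masks entry needs a 'kind'")

    # training --------------------------------------------------------------
    train_sec = {**_TRAINING_DEFAULTS, **raw.get("training", {})}
    _check_keys(raw.get("training", {}), _TRAINING_DEFAULTS, "training")
    master_seed = int(raw.get("master_seed", 0))
    loss_spec = LossSpec(**{k: train_sec[k] for k in _LOSS_KEYS})
    train_cfg = TrainConfig(
        master_seed=master_seed,
        **{k: train_sec[k] for k in _TRAINING_DEFAULTS if k not in _LOSS_KEYS})

    # curriculum ------------------------------------------------------------
    curriculum = None
    cur_sec = raw.get("curriculum")
    if cur_sec is not None:
        _check_keys(cur_sec, ("coherences", "threshold"), "curriculum")
        if name != "perceptual_discrimination":
            raise ValueError("the coherence curriculum requires "
                             "task.name=perceptual_discrimination")
        curriculum = make_coherence_curriculum(
            cur_sec["coherences"], cur_sec.get("threshold", 0.9),
            base_cfg=task.config)

    resolved = {
        "task": {"name": name,
                 **{f.name: getattr(task.config, f.name)
                    for f in dataclasses.fields(task.config)}},
        "network": {k: net_sec[k] for k in _NETWORK_DEFAULTS},
        "training": {k: train_sec[k] for k in _TRAINING_DEFAULTS},
        "curriculum": dict(cur_sec) if cur_sec is not None else None,
        "output_dir": raw.get("output_dir", "runs"),
        "master_seed": master_seed,
    }
    resolved = json.loads(json.dumps(resolved))  # plain JSON types only

    return RunConfig(
        task=task, task_name=name, net_spec=net_spec, loss_spec=loss_spec,
        train_cfg=train_cfg, curriculum=curriculum,
        mask_recipes=mask_recipes, initializer=net_sec["initializer"],
        init_radius=net_sec["init_radius"], init_alpha=net_sec["init_alpha"],
        output_dir=resolved["output_dir"], master_seed=master_seed,
        resolved=resolved)


def build_network(run: RunConfig, rng: np.random.Generator):
    """Initialize weights and masks per the run config (initializer choice
    plus structured-mask recipes, applied in order)."""
    w, m = default_initializer(run.net_spec, rng, radius=run.init_radius)
    if run.initializer == "alpha_identity":
        w.W_rec_raw = init_alpha_identity(run.net_spec.n_rec, run.init_alpha)
    for recipe in run.mask_recipes:
        kw = {k: v for k, v in recipe.items() if k != "kind"}
        if "region_sizes" in kw:
            kw["region_sizes"] = tuple(kw["region_sizes"])
        m = make_structured_masks(recipe["kind"], m, rng=rng, **kw)
    return w, m


# ---------------------------------------------------------------------------
# Weight archives
# ---------------------------------------------------------------------------

def _encode_array(arr: np.ndarray) -> dict:
    return {"shape": list(arr.shape), "data": arr.ravel().tolist()}


def _decode_array(obj: dict) -> np.ndarray:
    arr = np.asarray(obj["data"], dtype=float)
    return arr.reshape(obj["shape"])


def save_weights(path: str, w: WeightSet, m: MaskSet, spec: NetworkSpec):
    """Losslessly archive weights, masks and spec as a JSON document."""
    doc = {
        "format": WEIGHT_FORMAT,
        "version": WEIGHT_VERSION,
        "spec": spec.to_dict(),
        "weights": {k: _encode_array(getattr(w, k)) for k in
                    ("W_in_raw", "W_rec_raw", "W_out_raw", "b_rec", "b_out", "x0")},
        "masks": {k: _encode_array(getattr(m, k)) for k in
                  ("conn_in", "conn_rec", "conn_out", "train_in", "train_rec",
                   "train_out", "train_b_rec", "train_b_out")},
        "dale_signs": (None if m.dale_signs is None
                       else _encode_array(m.dale_signs)),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)
        fh.write("\n")


def load_weights(path: str):
    """Load a weight archive; returns ``(WeightSet, MaskSet, NetworkSpec)``.

    Raises on version mismatch or on arrays whose shapes disagree with the
    stored spec.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != WEIGHT_FORMAT:
        raise ValueError(f"{path} is not a {WEIGHT_FORMAT} archive")
    if doc.get("version") != WEIGHT_VERSION:
        raise ValueError(f"archive version {doc.get('version')} unsupported "
                         f"(expected {WEIGHT_VERSION})")
    spec = NetworkSpec.from_dict(doc["spec"])
    w = WeightSet(**{k: _decode_array(v) for k, v in doc["weights"].items()})
    signs = doc.get("dale_signs")
    m = MaskSet(**{k: _decode_array(v) for k, v in doc["masks"].items()},
                dale_signs=None if signs is None else _decode_array(signs))
    expected = {
        "W_in_raw": (spec.n_rec, spec.n_in),
        "W_rec_raw": (spec.n_rec, spec.n_rec),
        "W_out_raw": (spec.n_out, spec.n_rec),
        "b_rec": (spec.n_rec,), "b_out": (spec.n_out,), "x0": (spec.n_rec,),
    }
    for name, shape in expected.items():
        if getattr(w, name).shape != shape:
            raise ValueError(f"archive corrupt: {name} has shape "
                             f"{getattr(w, name).shape}, expected {shape}")
    return w, m, spec


def save_batch(path: str, batch: Batch):
    """Export a batch as an npz archive (arrays ``inputs``, ``targets``,
    ``mask``) with a JSON sidecar of the trial params."""
    np.savez(path, inputs=batch.inputs, targets=batch.targets,
             mask=batch.mask)
    sidecar = os.fspath(path)
    sidecar = sidecar[:-4] if sidecar.endswith(".npz") else sidecar
    with open(sidecar + ".params.json", "w") as fh:
        json.dump(batch.params, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureSet:
    """A tiny deterministic network plus a precomputed trajectory and loss,
    regenerable bit-identically from the fixed seed."""

    w: WeightSet
    m: MaskSet
    spec: NetworkSpec
    inputs: np.ndarray
    noise: np.ndarray
    states: np.ndarray
    rates: np.ndarray
    outputs: np.ndarray
    loss: float


FIXTURE_SEED = 20210105


def make_fixture_set(seed: int = FIXTURE_SEED) -> FixtureSet:
    from .network import forward
    from .training import masked_mse

    spec = NetworkSpec(n_in=2, n_rec=4, n_out=2, dt=10.0, tau=100.0,
                       sigma_rec=0.05, dales_ratio=0.75)
    rng = np.random.default_rng(seed)
    w, m = default_initializer(spec, rng)
    T = 12
    inputs = rng.standard_normal((1, T, spec.n_in)) * 0.5
    noise = rng.standard_normal((1, T, spec.n_rec))
    states, rates, outputs = forward(inputs, w, m, spec, noise=noise)
    targets = np.zeros_like(outputs)
    mask = np.ones_like(outputs)
    loss = masked_mse(outputs, targets, mask)
    return FixtureSet(w=w, m=m, spec=spec, inputs=inputs, noise=noise,
                      states=states, rates=rates, outputs=outputs, loss=loss)


def write_fixtures(directory: str, seed: int = FIXTURE_SEED) -> dict:
    """Regenerate the fixture set on disk; returns the paths written."""
    os.makedirs(directory, exist_ok=True)
    fx = make_fixture_set(seed)
    weights_path = os.path.join(directory, "fixture_weights.json")
    save_weights(weights_path, fx.w, fx.m, fx.spec)
    traj_path = os.path.join(directory, "fixture_trajectory.npz")
    np.savez(traj_path, inputs=fx.inputs, noise=fx.noise, states=fx.states,
             rates=fx.rates, outputs=fx.outputs, loss=fx.loss)
    return {"weights": weights_path, "trajectory": traj_path}
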