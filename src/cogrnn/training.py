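"""Masked losses, regularizers, backpropagation through time, optimizers,
and the training loop.

Gradients are computed by explicit reverse-mode differentiation through the
unrolled Euler-Maruyama recurrence (see :mod:`cogrnn.network`).  Noise
realizations are treated as constants for the gradient evaluation (pathwise
derivative): each iteration draws one noise tensor, runs the forward pass
with it, and backpropagates through exactly that realization.  The chain
rule runs through the constraint reparameterization as well, so the returned
gradients are with respect to the *raw* parameters: under Dale's principle
``dL/dW_raw = dL/dW_eff * conn * sign(W_raw) * s_pre`` (subgradient 0 at
``W_raw = 0``), without Dale simply ``dL/dW_eff * conn``.

Losses are averaged, not summed: the masked mean-squared error is
``sum(mask * (z - y)^2) / sum(mask)`` over the whole batch, so learning
rates do not depend on batch size or trial length.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import (MaskSet, NetworkSpec, WeightSet, _TRANSFERS,
                      effective_weights, forward)
from .task import Batch, assemble_batch

__all__ = [
    "LossSpec",
    "TrainConfig",
    "TrainingTrace",
    "seed_streams",
    "masked_mse",
    "masked_bce",
    "regularization_penalty",
    "total_loss",
    "compute_gradients",
    "apply_constraints_to_grads",
    "init_optimizer_state",
    "optimizer_step",
    "train",
]

_BCE_EPS = 1e-7
_TRAINABLE = ("W_in_raw", "W_rec_raw", "W_out_raw", "b_rec", "b_out")
_TRAIN_MASK_OF = {"W_in_raw": "train_in", "W_rec_raw": "train_rec",
                  "W_out_raw": "train_out", "b_rec": "train_b_rec",
                  "b_out": "train_b_out"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class LossSpec:
    """Loss choice and regularization coefficients (all off by default)."""

    loss: str = "mean_squared_error"
    lambda_l1_w: float = 0.0
    lambda_l2_w: float = 0.0
    lambda_l2_rate: float = 0.0

    def __post_init__(self):
        if self.loss not in ("mean_squared_error", "binary_cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if min(self.lambda_l1_w, self.lambda_l2_w, self.lambda_l2_rate) < 0:
            raise ValueError("regularization coefficients must be >= 0")


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    n_iterations: int = 1000
    batch_size: int = 64
    eval_every: int = 10
    eval_batch: int = 128
    grad_clip_norm: float | None = None
    master_seed: int = 0

    def __post_init__(self):
        if self.optimizer not in ("sgd", "adam", "rmsprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for name in ("batch_size", "eval_every", "eval_batch"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.grad_clip_norm is not None and self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be positive when set")


@dataclass
class TrainingTrace:
    """Loss/accuracy recorded on fresh evaluation batches every
    ``eval_every`` iterations (plus the curriculum stage active then)."""

    iterations: list[int] = field(default_factory=list)
    loss_values: list[float] = field(default_factory=list)
    accuracy_values: list[float] = field(default_factory=list)
    stage_indices: list[int] = field(default_factory=list)
    curriculum_state: object | None = None

    def record(self, iteration, loss, acc, stage):
        self.iterations.append(int(iteration))
        self.loss_values.append(float(loss))
        self.accuracy_values.append(float(acc))
        self.stage_indices.append(int(stage))

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "loss", "accuracy", "stage"])
            for row in zip(self.iterations, self.loss_values,
                           self.accuracy_values, self.stage_indices):
                writer.writerow(row)


def seed_streams(master_seed: int, names=("init", "trials", "noise",
                                          "eval_trials", "eval_noise")):
    """Fan one master seed out into named independent random streams, so
    e.g. changing the evaluation cadence never perturbs training draws."""
    children = np.random.SeedSequence(master_seed).spawn(len(names))
    return {name: np.random.default_rng(child)
            for name, child in zip(names, children)}


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def masked_mse(outputs, targets, mask) -> float:
    """Mask-weighted mean squared error; 0 for an all-zero mask."""
    outputs, targets, mask = (np.asarray(a, dtype=float)
                              for a in (outputs, targets, mask))
    total = mask.sum()
    if total == 0:
        return 0.0
    return float((mask * (outputs - targets) ** 2).sum() / total)


def _mse_grad(outputs, targets, mask):
    total = mask.sum()
    if total == 0:
        return np.zeros_like(outputs)
    return 2.0 * mask * (outputs - targets) / total


def masked_bce(outputs, targets, mask) -> float:
    """Mask-weighted binary cross-entropy of the logistic-squashed raw
    outputs, with probabilities clipped to ``[1e-7, 1 - 1e-7]``."""
    outputs, targets, mask = (np.asarray(a, dtype=float)
                              for a in (outputs, targets, mask))
    if np.any(targets < 0) or np.any(targets > 1):
        raise ValueError("binary_cross_entropy targets must lie in [0, 1]")
    total = mask.sum()
    if total == 0:
        return 0.0
    p = np.clip(_sigmoid(outputs), _BCE_EPS, 1.0 - _BCE_EPS)
    nll = -(targets * np.log(p) + (1.0 - targets) * np.log(1.0 - p))
    return float((mask * nll).sum() / total)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _bce_grad(outputs, targets, mask):
    total = mask.sum()
    if total == 0:
        return np.zeros_like(outputs)
    p = _sigmoid(outputs)
    inside = (p > _BCE_EPS) & (p < 1.0 - _BCE_EPS)
    pc = np.clip(p, _BCE_EPS, 1.0 - _BCE_EPS)
    dnll_dp = -targets / pc + (1.0 - targets) / (1.0 - pc)
    return mask * dnll_dp * inside * p * (1.0 - p) / total


_LOSSES = {"mean_squared_error": (masked_mse, _mse_grad),
           "binary_cross_entropy": (masked_bce, _bce_grad)}


def regularization_penalty(w: WeightSet, m: MaskSet, rates,
                           spec: LossSpec) -> float:
    """L1/L2 penalties on the effective weight matrices plus an L2 penalty
    on the mean squared firing rate."""
    penalty = 0.0
    if spec.lambda_l1_w or spec.lambda_l2_w:
        for W in effective_weights(w, m):
            penalty += spec.lambda_l1_w * np.abs(W).sum()
            penalty += spec.lambda_l2_w * (W ** 2).sum()
    if spec.lambda_l2_rate:
        penalty += spec.lambda_l2_rate * float(np.mean(np.asarray(rates) ** 2))
    return float(penalty)


def total_loss(outputs, targets, mask, w, m, rates, spec: LossSpec) -> float:
    base = _LOSSES[spec.loss][0](outputs, targets, mask)
    return base + regularization_penalty(w, m, rates, spec)


# ---------------------------------------------------------------------------
# Backpropagation through time
# ---------------------------------------------------------------------------

def compute_gradients(w: WeightSet, m: MaskSet, batch: Batch,
                      net_spec: NetworkSpec, loss_spec: LossSpec,
                      noise: np.ndarray):
    """Forward pass plus reverse-mode gradients of the total loss.

    Parameters
    ----------
    noise
        The ``(B, T, n_rec)`` standard-normal tensor used for this forward
        pass; the same draw must be reused when checking gradients by
        finite differences.

    Returns
    -------
    grads, loss, outputs, rates
        ``grads`` maps each raw trainable parameter name to its gradient
        (same shape as the parameter).
    """
    inputs, targets, mask = batch.inputs, batch.targets, batch.mask
    B, T, _ = inputs.shape
    a = net_spec.alpha
    noise_scale = math.sqrt(2.0 * a) * net_spec.sigma_rec
    f, df = _TRANSFERS[net_spec.transfer]
    W_in, W_rec, W_out = effective_weights(w, m)

    # forward pass, keeping the state history for the backward sweep
    xs = np.empty((B, T, net_spec.n_rec))
    rs = np.empty((B, T, net_spec.n_rec))
    x = np.broadcast_to(w.x0, (B, net_spec.n_rec)).copy()
    r0 = f(x)
    r = r0
    for t in range(T):
        x = ((1.0 - a) * x + a * (r @ W_rec.T + w.b_rec + inputs[:, t] @ W_in.T)
             + noise_scale * noise[:, t])
        r = f(x)
        xs[:, t] = x
        rs[:, t] = r
    if not np.all(np.isfinite(xs)):
        raise FloatingPointError("recurrent state diverged during training")
    outputs = rs @ W_out.T + w.b_out

    base_loss, grad_fn = _LOSSES[loss_spec.loss]
    loss = base_loss(outputs, targets, mask)
    dz = grad_fn(outputs, targets, mask)          # (B, T, n_out)

    # readout
    dW_out_eff = np.einsum("btj,btk->jk", dz, rs)
    db_out = dz.sum(axis=(0, 1))
    dr = dz @ W_out                               # (B, T, n_rec)
    if loss_spec.lambda_l2_rate:
        dr = dr + (2.0 * loss_spec.lambda_l2_rate / rs.size) * rs

    # reverse sweep through the recurrence
    dW_rec_eff = np.zeros_like(W_rec)
    dW_in_eff = np.zeros_like(W_in)
    db_rec = np.zeros(net_spec.n_rec)
    dx_next = np.zeros((B, net_spec.n_rec))
    for t in range(T - 1, -1, -1):
        dr_t = dr[:, t] + a * (dx_next @ W_rec)
        dx_t = dr_t * df(xs[:, t]) + (1.0 - a) * dx_next
        r_pre = rs[:, t - 1] if t > 0 else r0
        dW_rec_eff += a * (dx_t.T @ r_pre)
        dW_in_eff += a * (dx_t.T @ inputs[:, t])
        db_rec += a * dx_t.sum(axis=0)
        dx_next = dx_t

    # weight regularizers act on the effective weights
    if loss_spec.lambda_l1_w or loss_spec.lambda_l2_w:
        for dW, W in ((dW_in_eff, W_in), (dW_rec_eff, W_rec),
                      (dW_out_eff, W_out)):
            dW += loss_spec.lambda_l1_w * np.sign(W)
            dW += 2.0 * loss_spec.lambda_l2_w * W

    # chain through the constraint reparameterization to the raw parameters
    dW_in_raw = dW_in_eff * m.conn_in
    if m.dale_signs is None:
        dW_rec_raw = dW_rec_eff * m.conn_rec
        dW_out_raw = dW_out_eff * m.conn_out
    else:
        s = m.dale_signs[None, :]
        dW_rec_raw = dW_rec_eff * m.conn_rec * s * np.sign(w.W_rec_raw)
        dW_out_raw = dW_out_eff * m.conn_out * s * np.sign(w.W_out_raw)

    grads = {"W_in_raw": dW_in_raw, "W_rec_raw": dW_rec_raw,
             "W_out_raw": dW_out_raw, "b_rec": db_rec, "b_out": db_out}
    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for {name}")
    loss = loss + regularization_penalty(w, m, rs, loss_spec)
    return grads, float(loss), outputs, rs


def apply_constraints_to_grads(grads: dict, m: MaskSet) -> dict:
    """Zero gradients of frozen parameters (trainability mask 0)."""
    return {name: g * getattr(m, _TRAIN_MASK_OF[name])
            for name, g in grads.items()}


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8
_RMSPROP_DECAY, _RMSPROP_EPS = 0.9, 1e-8


def init_optimizer_state(cfg: TrainConfig, params: dict) -> dict:
    state = {"t": 0}
    if cfg.optimizer == "adam":
        state["m"] = {k: np.zeros_like(v) for k, v in params.items()}
        state["v"] = {k: np.zeros_like(v) for k, v in params.items()}
    elif cfg.optimizer == "rmsprop":
        state["v"] = {k: np.zeros_like(v) for k, v in params.items()}
    return state


def _clip_global_norm(grads: dict, max_norm: float) -> dict:
    norm = math.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if norm > max_norm:
        scale = max_norm / norm
        return {k: g * scale for k, g in grads.items()}
    return grads


def optimizer_step(state: dict, params: dict, grads: dict,
                   cfg: TrainConfig) -> tuple[dict, dict]:
    """One parameter update; returns fresh state and parameter dicts.

    Update rules: plain SGD; Adam with beta1=0.9, beta2=0.999, eps=1e-8 and
    bias correction; RMSProp with decay 0.9 and ``p -= lr g / (sqrt(v)+eps)``.
    Optional global-norm gradient clipping precedes the update.
    """
    if cfg.grad_clip_norm is not None:
        grads = _clip_global_norm(grads, cfg.grad_clip_norm)
    lr = cfg.learning_rate
    t = state["t"] + 1
    new_params = {}
    new_state = {"t": t}
    if cfg.optimizer == "sgd":
        for k, p in params.items():
            new_params[k] = p - lr * grads[k]
    elif cfg.optimizer == "adam":
        new_state["m"], new_state["v"] = {}, {}
        for k, p in params.items():
            mk = _ADAM_B1 * state["m"][k] + (1 - _ADAM_B1) * grads[k]
            vk = _ADAM_B2 * state["v"][k] + (1 - _ADAM_B2) * grads[k] ** 2
            m_hat = mk / (1 - _ADAM_B1 ** t)
            v_hat = vk / (1 - _ADAM_B2 ** t)
            new_params[k] = p - lr * m_hat / (np.sqrt(v_hat) + _ADAM_EPS)
            new_state["m"][k], new_state["v"][k] = mk, vk
    elif cfg.optimizer == "rmsprop":
        new_state["v"] = {}
        for k, p in params.items():
            vk = _RMSPROP_DECAY * state["v"][k] + (1 - _RMSPROP_DECAY) * grads[k] ** 2
            new_params[k] = p - lr * grads[k] / (np.sqrt(vk) + _RMSPROP_EPS)
            new_state["v"][k] = vk
    return new_state, new_params


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(w: WeightSet, m: MaskSet, task, net_spec: NetworkSpec,
          loss_spec: LossSpec, cfg: TrainConfig, curriculum=None):
    """Train the network on ``task`` (or on ``curriculum``'s stages).

    Each iteration samples a fresh batch, runs the stochastic forward pass,
    backpropagates, applies the trainability masks to the gradients and
    updates the raw parameters.  Every ``eval_every`` iterations loss and
    accuracy are measured on a freshly sampled evaluation batch (from
    separate random streams) and recorded; with a curriculum, the stage
    metric is evaluated there and stage advancement may fire.  Training
    stops early when the curriculum completes.

    Returns the final :class:`WeightSet` and the :class:`TrainingTrace`
    (which carries the final curriculum state, if any).  Fully reproducible
    from ``cfg.master_seed``.
    """
    from .curriculum import CurriculumState, advance, evaluate_metric, should_advance

    w = w.copy()
    params = {k: getattr(w, k) for k in _TRAINABLE}
    x0 = w.x0  # non-trainable initial state
    streams = seed_streams(cfg.master_seed)
    opt_state = init_optimizer_state(cfg, params)
    trace = TrainingTrace()

    state = None
    if curriculum is not None:
        state = CurriculumState()
        current_task = curriculum.stages[0]
    else:
        if task is None:
            raise ValueError("either a task or a curriculum is required")
        current_task = task

    if current_task.n_in != net_spec.n_in or current_task.n_out != net_spec.n_out:
        raise ValueError("task channel counts do not match network spec")

    for it in range(1, cfg.n_iterations + 1):
        batch = assemble_batch(current_task, cfg.batch_size, streams["trials"])
        noise = streams["noise"].standard_normal(
            (cfg.batch_size, current_task.T, net_spec.n_rec))
        grads, loss, _, _ = compute_gradients(w, m, batch, net_spec,
                                              loss_spec, noise)
        if not math.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at iteration {it}")
        grads = apply_constraints_to_grads(grads, m)
        opt_state, params = optimizer_step(opt_state, params, grads, cfg)
        w = WeightSet(**params, x0=x0)

        if it % cfg.eval_every == 0:
            eval_batch = assemble_batch(current_task, cfg.eval_batch,
                                        streams["eval_trials"])
            eval_noise = streams["eval_noise"].standard_normal(
                (cfg.eval_batch, current_task.T, net_spec.n_rec))
            _, _, outputs = forward(eval_batch.inputs, w, m, net_spec,
                                    noise=eval_noise)
            eval_loss = _LOSSES[loss_spec.loss][0](
                outputs, eval_batch.targets, eval_batch.mask)
            acc = current_task.accuracy(outputs, eval_batch)
            stage = state.stage_index if state is not None else 0
            trace.record(it, eval_loss, acc, stage)
            if curriculum is not None and not state.complete:
                metric_value = evaluate_metric(curriculum, outputs,
                                               eval_batch, current_task,
                                               accuracy_value=acc)
                if should_advance(state, metric_value, curriculum):
                    state = advance(state, curriculum, it)
                    if state.complete:
                        break
                    current_task = curriculum.stages[state.stage_index]
                    if (current_task.n_in != net_spec.n_in
                            or current_task.n_out != net_spec.n_out):
                        raise ValueError("curriculum stage channel counts "
                                         "do not match network spec")

    if curriculum is not None and not state.complete:
        warnings.warn("n_iterations elapsed before the curriculum completed",
                      RuntimeWarning, stacklevel=2)
    trace.curriculum_state = state
    return w, trace
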