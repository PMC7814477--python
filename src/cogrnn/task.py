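"""Cognitive-task contract and batch assembly.

A task is defined by two functions: ``generate_trial_params`` draws the
condition of one trial (stimulus strength, correct response, the trial's own
noise seed, ...) and ``trial_function`` returns, for any time ``t`` within
the trial, the input vector, the target output vector and the output mask.
The mask is a nonnegative per-channel loss weight: 0 leaves the network
unconstrained at that time (e.g. while the stimulus is on), 1 applies the
full penalty.  Trials are rasterized on the grid ``t_k = k * dt``,
``k = 0 .. T-1`` with ``T = round(trial_duration / dt)``, and stacked into
batches for training.

Per-trial correctness (and hence task accuracy, the fraction of correct
trials in a batch) is task-defined; the bundled tasks score the time-averaged
output over the response window by argmax, ties broken toward the lowest
channel index.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrialTensors",
    "Batch",
    "Task",
    "generate_trial_params",
    "trial_function",
    "assemble_trial",
    "assemble_batch",
    "accuracy",
]

MAX_TRIAL_SEED = 2 ** 31


@dataclass
class TrialTensors:
    """One trial's input, target-output, and output-mask time series."""

    inputs: np.ndarray   # (T, n_in)
    targets: np.ndarray  # (T, n_out)
    mask: np.ndarray     # (T, n_out), entries >= 0

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        self.mask = np.asarray(self.mask, dtype=float)
        T = self.inputs.shape[0]
        if self.targets.shape[0] != T or self.mask.shape[0] != T:
            raise ValueError("inputs, targets and mask must share leading dimension")
        if self.targets.shape != self.mask.shape:
            raise ValueError("targets and mask must have identical shapes")
        for name in ("inputs", "targets", "mask"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.mask < 0):
            raise ValueError("mask entries must be nonnegative")


@dataclass
class Batch:
    """A stack of trials: ``(B, T, n_in)`` inputs, ``(B, T, n_out)`` targets
    and mask, plus the per-trial parameter dictionaries."""

    inputs: np.ndarray
    targets: np.ndarray
    mask: np.ndarray
    params: list[dict]

    def __post_init__(self):
        if self.inputs.shape[0] < 1:
            raise ValueError("batch must contain at least one trial")
        if not (self.inputs.shape[0] == self.targets.shape[0]
                == self.mask.shape[0] == len(self.params)):
            raise ValueError("batch dimensions inconsistent")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def trial(self, i: int) -> TrialTensors:
        return TrialTensors(self.inputs[i], self.targets[i], self.mask[i])


class Task(ABC):
    """Abstract cognitive task.

    Subclasses fix ``n_in``/``n_out``, the trial schedule, and implement
    :meth:`generate_trial_params` and :meth:`trial_function`.  The default
    :meth:`assemble_trial` rasterizes ``trial_function`` over the time grid;
    subclasses may override it with a vectorized equivalent, which must be
    bit-identical to the loop.
    """

    def __init__(self, n_in: int, n_out: int, dt: float, trial_duration: float):
        if n_in < 1 or n_out < 1:
            raise ValueError("n_in and n_out must be >= 1")
        if dt <= 0 or trial_duration <= 0:
            raise ValueError("dt and trial_duration must be positive")
        self.n_in = int(n_in)
        self.n_out = int(n_out)
        self.dt = float(dt)
        #: number of time steps; trial_duration is rounded to a multiple of dt
        self.T = int(round(trial_duration / dt))
        if self.T < 1:
            raise ValueError("trial_duration shorter than one time step")
        self.trial_duration = self.T * self.dt

    # -- per-trial contract -------------------------------------------------

    @abstractmethod
    def generate_trial_params(self, trial_index: int,
                              rng: np.random.Generator) -> dict:
        """Draw the complete parameter dictionary of one trial (must include
        an integer ``trial_seed`` making the trial reproducible on its own)."""

    @abstractmethod
    def trial_function(self, t: float, params: dict):
        """Input, target and mask vectors at time ``t`` (ms) of the trial."""

    def _check_time(self, t: float) -> int:
        if not 0.0 <= t < self.trial_duration:
            raise ValueError(
                f"t={t} outside trial bounds [0, {self.trial_duration})")
        return int(t // self.dt)

    # -- assembly -----------------------------------------------------------

    def assemble_trial(self, params: dict) -> TrialTensors:
        inputs = np.empty((self.T, self.n_in))
        targets = np.empty((self.T, self.n_out))
        mask = np.empty((self.T, self.n_out))
        for k in range(self.T):
            u, y, w = self.trial_function(k * self.dt, params)
            inputs[k], targets[k], mask[k] = u, y, w
        return TrialTensors(inputs, targets, mask)

    def assemble_batch(self, B: int, rng: np.random.Generator) -> Batch:
        if B < 1:
            raise ValueError("batch size must be >= 1")
        params = [self.generate_trial_params(i, rng) for i in range(B)]
        trials = [self.assemble_trial(p) for p in params]
        return Batch(
            inputs=np.stack([tr.inputs for tr in trials]),
            targets=np.stack([tr.targets for tr in trials]),
            mask=np.stack([tr.mask for tr in trials]),
            params=params,
        )

    # -- scoring ------------------------------------------------------------

    def correct_trial(self, output: np.ndarray, params: dict) -> bool:
        """Whether one trial's ``(T, n_out)`` output is a success."""
        raise NotImplementedError(
            f"{type(self).__name__} defines no accuracy function")

    def accuracy(self, outputs: np.ndarray, batch: Batch) -> float:
        outputs = np.asarray(outputs, dtype=float)
        if outputs.shape != batch.targets.shape:
            raise ValueError("outputs shape does not match batch")
        n_correct = sum(
            self.correct_trial(outputs[i], batch.params[i])
            for i in range(len(batch)))
        return n_correct / len(batch)


# ---------------------------------------------------------------------------
# Module-level operation surface (thin delegates)
# ---------------------------------------------------------------------------

def generate_trial_params(task: Task, trial_index: int,
                          rng: np.random.Generator) -> dict:
    return task.generate_trial_params(trial_index, rng)


def trial_function(task: Task, t: float, params: dict):
    return task.trial_function(t, params)


def assemble_trial(task: Task, params: dict,
                   rng: np.random.Generator | None = None) -> TrialTensors:
    # rng accepted for signature symmetry; trials are fully determined by
    # their params (which carry trial_seed)
    return task.assemble_trial(params)


def assemble_batch(task: Task, B: int, rng: np.random.Generator) -> Batch:
    return task.assemble_batch(B, rng)


def accuracy(task: Task, outputs: np.ndarray, batch: Batch) -> float:
    return task.accuracy(outputs, batch)
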