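"""Bundled cognitive tasks.

Three tasks standard in the systems-neuroscience literature are provided,
each as a config dataclass plus a :class:`~cogrnn.task.Task` subclass:

* **Perceptual discrimination** — two-alternative forced choice.  Two noisy
  input channels straddle 0.5 with means ``(1 +/- c) / 2`` where ``c`` is
  the stimulus coherence; the network reports the stronger channel during
  the response window.
* **Delayed discrimination** — a single input channel carries two amplitude
  pulses (frequencies ``f1`` then ``f2``, normalized by the largest
  configured frequency) separated by a delay; the network reports which was
  larger.
* **Delayed match-to-category** — ``n_directions`` one-hot input channels; a
  sample and a test direction are shown with a delay between them, and the
  network reports the category of the test direction under an equal-width
  partition ``category(k) = floor(k * n_categories / n_directions)``.
  Whether sample and test categories match is recorded per trial.

Input noise, where used, has per-step standard deviation
``noise_scale * sqrt(2 tau / dt)`` so that the information per unit of real
time is independent of the integration step.  Output masks are 0 while a
stimulus is on (the network is unconstrained there) and 1 during fixation,
delays and the response window; targets are 0 everywhere except the response
window.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .task import Task, TrialTensors

__all__ = [
    "PerceptualDiscriminationConfig",
    "PerceptualDiscrimination",
    "DelayedDiscriminationConfig",
    "DelayedDiscrimination",
    "DelayedMatchToCategoryConfig",
    "DelayedMatchToCategory",
    "vary_task",
    "make_task",
    "TASK_REGISTRY",
]

MAX_TRIAL_SEED = 2 ** 31


def _auto_noise_sd(scale: float, dt: float, tau: float) -> float:
    return scale * math.sqrt(2.0 * tau / dt)


def _argmax_choice(output: np.ndarray, window: slice) -> int:
    """Time-averaged response-window output, argmax choice (ties -> lowest)."""
    return int(np.argmax(np.asarray(output)[window].mean(axis=0)))


# ---------------------------------------------------------------------------
# Perceptual discrimination (two-alternative forced choice)
# ---------------------------------------------------------------------------

@dataclass
class PerceptualDiscriminationConfig:
    """Two noisy channels; coherence ``c`` sets their mean separation."""

    coherences: tuple[float, ...] = (0.7, 0.5, 0.3, 0.1)
    dt: float = 10.0
    tau: float = 100.0
    fixation_duration: float = 100.0
    stimulus_duration: float = 1000.0
    response_duration: float = 200.0
    noise_scale: float = 0.1
    input_noise_sd: float | None = None  # None -> noise_scale * sqrt(2 tau/dt)
    n_in: int = 2
    n_out: int = 2

    def __post_init__(self):
        self.coherences = tuple(float(c) for c in self.coherences)
        if len(self.coherences) == 0:
            raise ValueError("coherence list must be nonempty")
        if any(not 0.0 <= c <= 1.0 for c in self.coherences):
            raise ValueError("coherences must lie in [0, 1]")
        for name in ("fixation_duration", "stimulus_duration", "response_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.input_noise_sd is None:
            self.input_noise_sd = _auto_noise_sd(self.noise_scale, self.dt, self.tau)
        if self.input_noise_sd < 0:
            raise ValueError("input_noise_sd must be nonnegative")
        if (self.n_in, self.n_out) != (2, 2):
            raise ValueError("perceptual discrimination is a 2-channel task")

    @property
    def trial_duration(self) -> float:
        return (self.fixation_duration + self.stimulus_duration
                + self.response_duration)


class PerceptualDiscrimination(Task):
    """Report which of two noisy input channels has the larger mean."""

    def __init__(self, config: PerceptualDiscriminationConfig | None = None,
                 **overrides):
        if config is None:
            config = PerceptualDiscriminationConfig(**overrides)
        elif overrides:
            config = vary_task(config, overrides)
        self.config = config
        super().__init__(config.n_in, config.n_out, config.dt,
                         config.trial_duration)
        c = config
        self._k_stim = int(round(c.fixation_duration / c.dt))
        self._k_resp = int(round((c.fixation_duration + c.stimulus_duration) / c.dt))

    @property
    def response_slice(self) -> slice:
        return slice(self._k_resp, self.T)

    def generate_trial_params(self, trial_index, rng):
        cfg = self.config
        return {
            "trial_index": int(trial_index),
            "coherence": float(rng.choice(cfg.coherences)),
            "direction": int(rng.integers(2)),
            "trial_seed": int(rng.integers(MAX_TRIAL_SEED)),
        }

    def _noise_matrix(self, params):
        rng = np.random.default_rng(params["trial_seed"])
        return rng.standard_normal((self.T, 2)) * self.config.input_noise_sd

    def trial_function(self, t, params):
        k = self._check_time(t)
        c, d = params["coherence"], params["direction"]
        if d not in (0, 1):
            raise ValueError(f"invalid direction {d!r}")
        u = np.zeros(2)
        y = np.zeros(2)
        w = np.ones(2)
        if self._k_stim <= k < self._k_resp:
            u[d] = (1.0 + c) / 2.0
            u[1 - d] = (1.0 - c) / 2.0
            if self.config.input_noise_sd > 0:
                u = u + self._noise_matrix(params)[k]
            w[:] = 0.0
        elif k >= self._k_resp:
            y[d] = 1.0
        return u, y, w

    def assemble_trial(self, params):
        # vectorized fast path; bit-identical to the base-class loop
        c, d = params["coherence"], params["direction"]
        if d not in (0, 1):
            raise ValueError(f"invalid direction {d!r}")
        T = self.T
        inputs = np.zeros((T, 2))
        targets = np.zeros((T, 2))
        mask = np.ones((T, 2))
        stim = slice(self._k_stim, self._k_resp)
        inputs[stim, d] = (1.0 + c) / 2.0
        inputs[stim, 1 - d] = (1.0 - c) / 2.0
        if self.config.input_noise_sd > 0:
            inputs[stim] = inputs[stim] + self._noise_matrix(params)[stim]
        mask[stim] = 0.0
        targets[self._k_resp:, d] = 1.0
        return TrialTensors(inputs, targets, mask)

    def correct_trial(self, output, params):
        return _argmax_choice(output, self.response_slice) == params["direction"]


# ---------------------------------------------------------------------------
# Delayed discrimination (two amplitudes across a delay)
# ---------------------------------------------------------------------------

@dataclass
class DelayedDiscriminationConfig:
    """One input channel, two amplitude pulses separated by a delay."""

    frequency_pairs: tuple[tuple[float, float], ...] = (
        (18.0, 10.0), (10.0, 18.0), (22.0, 14.0), (14.0, 22.0),
        (30.0, 22.0), (22.0, 30.0), (34.0, 26.0), (26.0, 34.0))
    dt: float = 10.0
    tau: float = 100.0
    fixation_duration: float = 100.0
    stimulus_duration: float = 300.0
    delay_duration: float = 500.0
    response_duration: float = 200.0
    input_noise_sd: float = 0.0
    n_in: int = 1
    n_out: int = 2

    def __post_init__(self):
        self.frequency_pairs = tuple(
            (float(f1), float(f2)) for f1, f2 in self.frequency_pairs)
        if len(self.frequency_pairs) == 0:
            raise ValueError("frequency_pairs must be nonempty")
        for f1, f2 in self.frequency_pairs:
            if f1 <= 0 or f2 <= 0:
                raise ValueError("frequencies must be positive")
            if f1 == f2:
                raise ValueError(f"degenerate pair f1 == f2 == {f1}")
        for name in ("fixation_duration", "stimulus_duration",
                     "delay_duration", "response_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.input_noise_sd < 0:
            raise ValueError("input_noise_sd must be nonnegative")
        if (self.n_in, self.n_out) != (1, 2):
            raise ValueError("delayed discrimination has 1 input, 2 outputs")

    @property
    def f_max(self) -> float:
        return max(max(p) for p in self.frequency_pairs)

    @property
    def trial_duration(self) -> float:
        return (self.fixation_duration + 2 * self.stimulus_duration
                + self.delay_duration + self.response_duration)


class DelayedDiscrimination(Task):
    """Report whether the first or second pulse had the larger amplitude
    (channel 0 wins iff ``f1 > f2``).  Amplitudes are ``f / f_max`` to keep
    inputs O(1)."""

    def __init__(self, config: DelayedDiscriminationConfig | None = None,
                 **overrides):
        if config is None:
            config = DelayedDiscriminationConfig(**overrides)
        elif overrides:
            config = vary_task(config, overrides)
        self.config = config
        super().__init__(config.n_in, config.n_out, config.dt,
                         config.trial_duration)
        c = config
        edges_ms = np.cumsum([c.fixation_duration, c.stimulus_duration,
                              c.delay_duration, c.stimulus_duration])
        # step indices of epoch starts: stim1, delay, stim2, response
        self._k_stim1, self._k_delay, self._k_stim2, self._k_resp = (
            int(round(e / c.dt)) for e in edges_ms)

    @property
    def response_slice(self) -> slice:
        return slice(self._k_resp, self.T)

    def generate_trial_params(self, trial_index, rng):
        cfg = self.config
        f1, f2 = cfg.frequency_pairs[rng.integers(len(cfg.frequency_pairs))]
        return {
            "trial_index": int(trial_index),
            "f1": f1,
            "f2": f2,
            "trial_seed": int(rng.integers(MAX_TRIAL_SEED)),
        }

    def _noise_matrix(self, params):
        rng = np.random.default_rng(params["trial_seed"])
        return rng.standard_normal((self.T, 1)) * self.config.input_noise_sd

    def trial_function(self, t, params):
        k = self._check_time(t)
        f1, f2 = params["f1"], params["f2"]
        if f1 == f2:
            raise ValueError("degenerate trial: f1 == f2")
        fmax = self.config.f_max
        u = np.zeros(1)
        y = np.zeros(2)
        w = np.ones(2)
        in_stim1 = self._k_stim1 <= k < self._k_delay
        in_stim2 = self._k_stim2 <= k < self._k_resp
        if in_stim1:
            u[0] = f1 / fmax
        elif in_stim2:
            u[0] = f2 / fmax
        if in_stim1 or in_stim2:
            if self.config.input_noise_sd > 0:
                u = u + self._noise_matrix(params)[k]
            w[:] = 0.0
        if k >= self._k_resp:
            y[0 if f1 > f2 else 1] = 1.0
        return u, y, w

    def correct_trial(self, output, params):
        winner = 0 if params["f1"] > params["f2"] else 1
        return _argmax_choice(output, self.response_slice) == winner


# ---------------------------------------------------------------------------
# Delayed match-to-category
# ---------------------------------------------------------------------------

@dataclass
class DelayedMatchToCategoryConfig:
    """One one-hot input channel per direction; one output per category."""

    n_directions: int = 8
    n_categories: int = 2
    dt: float = 10.0
    tau: float = 100.0
    fixation_duration: float = 100.0
    sample_duration: float = 300.0
    delay_duration: float = 500.0
    test_duration: float = 300.0
    response_duration: float = 200.0
    noise_scale: float = 0.1
    input_noise_sd: float | None = None

    def __post_init__(self):
        self.n_directions = int(self.n_directions)
        self.n_categories = int(self.n_categories)
        if self.n_directions < 2 or self.n_categories < 2:
            raise ValueError("need n_directions >= 2 and n_categories >= 2")
        if self.n_directions % self.n_categories != 0:
            raise ValueError("n_directions must be divisible by n_categories "
                             "(equal-width categories)")
        for name in ("fixation_duration", "sample_duration", "delay_duration",
                     "test_duration", "response_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.input_noise_sd is None:
            self.input_noise_sd = _auto_noise_sd(self.noise_scale, self.dt, self.tau)
        if self.input_noise_sd < 0:
            raise ValueError("input_noise_sd must be nonnegative")

    @property
    def n_in(self) -> int:
        return self.n_directions

    @property
    def n_out(self) -> int:
        return self.n_categories

    @property
    def trial_duration(self) -> float:
        return (self.fixation_duration + self.sample_duration
                + self.delay_duration + self.test_duration
                + self.response_duration)

    def category(self, direction: int) -> int:
        if not 0 <= direction < self.n_directions:
            raise ValueError(f"direction {direction} out of range "
                             f"[0, {self.n_directions})")
        return direction * self.n_categories // self.n_directions


class DelayedMatchToCategory(Task):
    """Report the category of the test direction; the trial's match label
    (same category as the sample) is recorded in its params."""

    def __init__(self, config: DelayedMatchToCategoryConfig | None = None,
                 **overrides):
        if config is None:
            config = DelayedMatchToCategoryConfig(**overrides)
        elif overrides:
            config = vary_task(config, overrides)
        self.config = config
        super().__init__(config.n_in, config.n_out, config.dt,
                         config.trial_duration)
        c = config
        k = lambda ms: int(round(ms / c.dt))
        self._k_sample = k(c.fixation_duration)
        self._k_delay = k(c.fixation_duration + c.sample_duration)
        self._k_test = k(c.fixation_duration + c.sample_duration
                         + c.delay_duration)
        self._k_resp = k(c.fixation_duration + c.sample_duration
                         + c.delay_duration + c.test_duration)

    @property
    def response_slice(self) -> slice:
        return slice(self._k_resp, self.T)

    def generate_trial_params(self, trial_index, rng):
        cfg = self.config
        sample = int(rng.integers(cfg.n_directions))
        test = int(rng.integers(cfg.n_directions))
        return {
            "trial_index": int(trial_index),
            "sample_dir": sample,
            "test_dir": test,
            "match": cfg.category(sample) == cfg.category(test),
            "trial_seed": int(rng.integers(MAX_TRIAL_SEED)),
        }

    def _noise_matrix(self, params):
        rng = np.random.default_rng(params["trial_seed"])
        return rng.standard_normal((self.T, self.n_in)) * self.config.input_noise_sd

    def trial_function(self, t, params):
        k = self._check_time(t)
        cfg = self.config
        sample, test = params["sample_dir"], params["test_dir"]
        u = np.zeros(self.n_in)
        y = np.zeros(self.n_out)
        w = np.ones(self.n_out)
        in_sample = self._k_sample <= k < self._k_delay
        in_test = self._k_test <= k < self._k_resp
        cfg.category(sample), cfg.category(test)  # range checks
        if in_sample:
            u[sample] = 1.0
        elif in_test:
            u[test] = 1.0
        if in_sample or in_test:
            if cfg.input_noise_sd > 0:
                u = u + self._noise_matrix(params)[k]
            w[:] = 0.0
        if k >= self._k_resp:
            y[cfg.category(test)] = 1.0
        return u, y, w

    def correct_trial(self, output, params):
        target = self.config.category(params["test_dir"])
        return _argmax_choice(output, self.response_slice) == target


# ---------------------------------------------------------------------------
# Config variation and registry
# ---------------------------------------------------------------------------

def vary_task(cfg, overrides: dict):
    """Return a new config with ``overrides`` applied; unknown keys raise.

    The original config is untouched, and dependent quantities (trial
    length, channel counts) are recomputed by the returned config/task.
    """
    valid = {f.name for f in dataclasses.fields(cfg)}
    unknown = set(overrides) - valid
    if unknown:
        raise KeyError(f"unknown config key(s) {sorted(unknown)} for "
                       f"{type(cfg).__name__}")
    return dataclasses.replace(cfg, **overrides)


TASK_REGISTRY = {
    "perceptual_discrimination": (PerceptualDiscrimination,
                                  PerceptualDiscriminationConfig),
    "delayed_discrimination": (DelayedDiscrimination,
                               DelayedDiscriminationConfig),
    "delayed_match_to_category": (DelayedMatchToCategory,
                                  DelayedMatchToCategoryConfig),
}


def make_task(name: str, **config_keys) -> Task:
    """Build a bundled task by registry name."""
    try:
        task_cls, cfg_cls = TASK_REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown task {name!r}; "
                         f"choose from {sorted(TASK_REGISTRY)}") from None
    return task_cls(cfg_cls(**config_keys))
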