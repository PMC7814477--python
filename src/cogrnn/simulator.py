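"""Standalone forward simulator and trained-network analyses.

:func:`simulate` re-implements the forward recurrence independently of the
training engine so perturbation experiments never touch training code; with
a shared noise stream it reproduces :func:`cogrnn.network.forward` exactly.
Supported perturbations: silencing units (rows, columns and readout of the
lesioned units zeroed), additive state pulses over a time window, and a
one-off Gaussian corruption of the recurrent weights.

Analyses mirror the standard treatment of a trained two-alternative
discrimination network: a psychometric function (logistic in signed
coherence, with a lapse rate) fitted to choice fractions, trial-averaged
correct-trial state traces per coherence, and PCA of the concatenated
averaged traces for state-space trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .network import MaskSet, NetworkSpec, WeightSet, _TRANSFERS, effective_weights
from .tasks import PerceptualDiscrimination

__all__ = [
    "Perturbation",
    "PsychometricFit",
    "simulate",
    "psychometric",
    "trial_averaged_states",
    "state_pca",
]


@dataclass
class Perturbation:
    """A perturbation applied during standalone simulation.

    kinds: ``lesion_units`` (silence ``targets``), ``state_pulse`` (add
    ``magnitude`` to the targeted units' state at every step with
    ``onset <= t < onset + duration``, ms), ``weight_noise`` (add i.i.d.
    N(0, magnitude) to the effective recurrent weights once).
    """

    kind: str
    targets: list[int] | np.ndarray | None = None
    magnitude: float = 0.0
    onset: float = 0.0
    duration: float = 0.0

    def __post_init__(self):
        if self.kind not in ("lesion_units", "state_pulse", "weight_noise"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    def unit_indices(self, n_rec: int) -> np.ndarray:
        idx = np.atleast_1d(np.asarray(self.targets, dtype=int))
        if idx.size and (idx.min() < 0 or idx.max() >= n_rec):
            raise ValueError(f"unit indices out of range [0, {n_rec})")
        return idx


@dataclass
class PsychometricFit:
    """Logistic-with-lapse psychometric fit:
    ``p(choice 0 | c) = lapse + (1 - 2 lapse) / (1 + exp(-k (c - c0)))``."""

    slope: float
    bias: float
    lapse: float
    choice_fractions: dict[float, float] = field(default_factory=dict)
    n_trials_per_level: int = 0

    def predict(self, signed_coherence):
        c = np.asarray(signed_coherence, dtype=float)
        return self.lapse + (1.0 - 2.0 * self.lapse) / (
            1.0 + np.exp(-self.slope * (c - self.bias)))


def simulate(w: WeightSet, m: MaskSet, net_spec: NetworkSpec,
             trial_inputs: np.ndarray, rng: np.random.Generator | None = None,
             noise: np.ndarray | None = None,
             perturbation: Perturbation | None = None):
    """Simulate the network on given inputs, optionally perturbed.

    ``trial_inputs`` is ``(T, n_in)`` for one trial or ``(B, T, n_in)`` for
    a batch.  Noise handling matches :func:`cogrnn.network.forward`: pass a
    generator (one ``(B, T, n_rec)`` standard-normal tensor is drawn) or the
    tensor itself.  With ``weight_noise`` the weight draw is taken from
    ``rng`` before the dynamics noise.
    """
    inputs = np.asarray(trial_inputs, dtype=float)
    single = inputs.ndim == 2
    if single:
        inputs = inputs[None]
    B, T, n_in = inputs.shape
    if n_in != net_spec.n_in:
        raise ValueError(f"inputs have {n_in} channels, spec.n_in={net_spec.n_in}")
    n_rec = net_spec.n_rec
    if w.W_rec_raw.shape != (n_rec, n_rec):
        raise ValueError("weight shapes do not match the network spec")

    W_in, W_rec, W_out = effective_weights(w, m)
    W_rec, W_out = W_rec.copy(), W_out.copy()
    pulse_units, pulse_window = None, None
    if perturbation is not None:
        if perturbation.kind == "weight_noise":
            if rng is None:
                raise ValueError("weight_noise perturbation requires rng")
            W_rec = W_rec + rng.normal(0.0, perturbation.magnitude, W_rec.shape)
        elif perturbation.kind == "lesion_units":
            idx = perturbation.unit_indices(n_rec)
            W_rec[idx, :] = 0.0
            W_rec[:, idx] = 0.0
            W_out[:, idx] = 0.0
        elif perturbation.kind == "state_pulse":
            pulse_units = perturbation.unit_indices(n_rec)
            pulse_window = (perturbation.onset,
                            perturbation.onset + perturbation.duration)

    if noise is None:
        if rng is not None:
            noise = rng.standard_normal((B, T, n_rec))
        else:
            noise = np.zeros((B, T, n_rec))
    else:
        noise = np.asarray(noise, dtype=float)
        if single and noise.ndim == 2:
            noise = noise[None]
        if noise.shape != (B, T, n_rec):
            raise ValueError("noise tensor shape mismatch")

    a = net_spec.alpha
    noise_scale = math.sqrt(2.0 * a) * net_spec.sigma_rec
    f = _TRANSFERS[net_spec.transfer][0]
    states = np.empty((B, T, n_rec))
    rates = np.empty((B, T, n_rec))
    x = np.broadcast_to(w.x0, (B, n_rec)).copy()
    r = f(x)
    for t in range(T):
        x = ((1.0 - a) * x + a * (r @ W_rec.T + w.b_rec + inputs[:, t] @ W_in.T)
             + noise_scale * noise[:, t])
        if pulse_units is not None:
            t_ms = t * net_spec.dt
            if pulse_window[0] <= t_ms < pulse_window[1]:
                x[:, pulse_units] += perturbation.magnitude
        r = f(x)
        states[:, t] = x
        rates[:, t] = r
    if not np.all(np.isfinite(states)):
        raise FloatingPointError("state diverged during simulation")
    outputs = rates @ W_out.T + w.b_out
    if single:
        return states[0], rates[0], outputs[0]
    return states, rates, outputs


def psychometric(task: PerceptualDiscrimination, w: WeightSet, m: MaskSet,
                 net_spec: NetworkSpec, coherences, trials_per_coherence: int,
                 rng: np.random.Generator) -> PsychometricFit:
    """Choice-1 (channel 0) fraction versus signed coherence, with a fitted
    logistic-with-lapse psychometric function.

    Positive signed coherence rewards choice 1 (direction 0), negative
    rewards choice 2.  Each unsigned coherence in ``coherences`` is tested
    at both signs with ``trials_per_coherence`` freshly simulated trials.
    """
    if trials_per_coherence < 1:
        raise ValueError("trials_per_coherence must be >= 1")
    levels = sorted({s for c in coherences for s in (-abs(float(c)), abs(float(c)))})
    fractions = {}
    for s in levels:
        params_list = []
        for _ in range(trials_per_coherence):
            direction = (0 if s > 0 else 1) if s != 0 else int(rng.integers(2))
            params_list.append({
                "coherence": abs(s),
                "direction": direction,
                "trial_seed": int(rng.integers(2 ** 31)),
            })
        inputs = np.stack([task.assemble_trial(p).inputs for p in params_list])
        _, _, outputs = simulate(w, m, net_spec, inputs, rng=rng)
        resp = outputs[:, task.response_slice].mean(axis=1)
        fractions[s] = float(np.mean(np.argmax(resp, axis=1) == 0))

    xs = np.array(sorted(fractions))
    ys = np.array([fractions[s] for s in xs])

    def residuals(theta):
        k, c0, lapse = theta
        pred = lapse + (1.0 - 2.0 * lapse) / (1.0 + np.exp(-k * (xs - c0)))
        return pred - ys

    fit = least_squares(residuals, x0=[5.0, 0.0, 0.01],
                        bounds=([-100.0, -1.0, 0.0], [100.0, 1.0, 0.5]))
    k, c0, lapse = fit.x
    return PsychometricFit(slope=float(k), bias=float(c0), lapse=float(lapse),
                           choice_fractions=fractions,
                           n_trials_per_level=trials_per_coherence)


def trial_averaged_states(states: np.ndarray, coherences, correct):
    """Per-coherence mean state traces over correct trials only.

    Parameters
    ----------
    states
        ``(N, T, n_rec)`` single-trial state traces.
    coherences, correct
        Per-trial coherence labels and correctness flags (length ``N``).

    Returns
    -------
    levels, traces
        Sorted unique coherence levels and a ``(n_levels, T, n_rec)`` array
        of correct-trial means.
    """
    states = np.asarray(states, dtype=float)
    coherences = np.asarray(coherences, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if states.shape[0] != coherences.shape[0] or states.shape[0] != correct.shape[0]:
        raise ValueError("states, coherences and correct must align")
    levels = np.unique(coherences)
    traces = np.empty((levels.size,) + states.shape[1:])
    for i, c in enumerate(levels):
        sel = (coherences == c) & correct
        if not np.any(sel):
            raise ValueError(f"coherence {c} has no correct trials")
        traces[i] = states[sel].mean(axis=0)
    return levels, traces


def state_pca(avg_traces: np.ndarray, n_project: int = 2):
    """PCA of trial-averaged traces concatenated across coherences.

    The ``(n_levels, T, n_rec)`` traces are stacked along time into a
    ``(n_levels * T, n_rec)`` matrix, columns (units) are mean-centered, and
    principal axes are extracted by SVD.

    Returns
    -------
    components
        ``(n_rec, n_components)`` orthonormal principal axes.
    explained
        Explained-variance fractions, non-increasing, summing to <= 1.
    projections
        ``(n_levels, T, n_project)`` trajectories in the top components.
    """
    traces = np.asarray(avg_traces, dtype=float)
    if traces.ndim != 3:
        raise ValueError("expected (n_levels, T, n_rec) traces")
    n_levels, T, n_rec = traces.shape
    X = traces.reshape(n_levels * T, n_rec)
    if X.shape[0] < 2:
        raise ValueError("need at least two time-coherence rows")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("rank-0 input: traces are constant")
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = svals ** 2
    explained = var / var.sum()
    components = Vt.T
    n_project = min(n_project, components.shape[1])
    projections = (Xc @ components[:, :n_project]).reshape(n_levels, T, n_project)
    return components, explained, projections
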