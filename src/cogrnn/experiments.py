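"""Bundled training experiments on the perceptual-discrimination task.

These drive the package end to end: train networks to a fixed accuracy
criterion, with and without a coherence-decreasing curriculum, and compare
iterations-to-criterion across paired random initializations with a
one-sided paired sign-rank test.  Problem sizes default to desk scale
(tens of recurrent units, minutes of CPU); see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .curriculum import make_coherence_curriculum
from .network import NetworkSpec, default_initializer, forward
from .task import assemble_batch
from .tasks import PerceptualDiscrimination, PerceptualDiscriminationConfig
from .training import LossSpec, TrainConfig, train

__all__ = [
    "experiment_pd_config",
    "train_to_criterion",
    "curriculum_comparison",
    "curriculum_final_accuracy",
]

#: trial schedule used by the bundled experiments (ms); the 900 ms stimulus
#: puts the lowest coherence (0.1) just above the 90% criterion for an ideal
#: integrator (~93%), so the hardest stage is genuinely near threshold
EXPERIMENT_SCHEDULE = dict(fixation_duration=100.0, stimulus_duration=900.0,
                           response_duration=200.0)
CURRICULUM_COHERENCES = (0.7, 0.5, 0.3, 0.1)


def experiment_train_config(train_seed: int, max_iterations: int) -> TrainConfig:
    """Training conditions for the criterion experiments: small batches put
    low-coherence learning in the gradient-noise-limited regime (as in
    trial-by-trial animal training), and the moderate learning rate spreads
    learning over hundreds of iterations so iterations-to-criterion is
    resolvable at the evaluation cadence; 512-trial criterion evaluations
    keep threshold detection reliable (binomial sd ~1.3%)."""
    return TrainConfig(optimizer="adam", learning_rate=2e-4, batch_size=16,
                       eval_every=20, eval_batch=512,
                       n_iterations=max_iterations, master_seed=train_seed)


def experiment_pd_config(coherences=(0.1,)) -> PerceptualDiscriminationConfig:
    return PerceptualDiscriminationConfig(coherences=tuple(coherences),
                                          **EXPERIMENT_SCHEDULE)


def train_to_criterion(stage_coherences, *, n_rec: int = 50,
                       threshold: float = 0.9, max_iterations: int = 8000,
                       init_seed: int, train_seed: int,
                       initial_weights=None, train_cfg: TrainConfig | None = None):
    """Train a network through a coherence curriculum until the final
    stage's accuracy threshold is reached (or ``max_iterations`` elapse).

    A single coherence in ``stage_coherences`` is plain training with a
    stopping criterion.  Returns a dict with the iterations-to-criterion
    (``max_iterations`` if the criterion was not reached), whether it was
    reached, the final weights/masks/spec and the training trace.
    """
    spec = NetworkSpec(n_in=2, n_rec=n_rec, n_out=2)
    if initial_weights is not None:
        w, m = initial_weights
        w = w.copy()
    else:
        w, m = default_initializer(spec, np.random.default_rng(init_seed))
    curriculum = make_coherence_curriculum(
        stage_coherences, threshold,
        base_cfg=experiment_pd_config((stage_coherences[0],)))
    if train_cfg is None:
        train_cfg = experiment_train_config(train_seed, max_iterations)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        w_final, trace = train(w, m, None, spec, LossSpec(), train_cfg,
                               curriculum=curriculum)
    state = trace.curriculum_state
    reached = state.complete
    iterations = (state.advancement_iterations[-1] if reached
                  else train_cfg.n_iterations)
    return {"reached": reached, "iterations": iterations, "weights": w_final,
            "masks": m, "spec": spec, "trace": trace,
            "curriculum_state": state}


def curriculum_comparison(seed: int, *, n_pairs: int = 10, n_rec: int = 40,
                          threshold: float = 0.9, max_iterations: int = 8000):
    """Paired curriculum-vs-fixed-coherence comparison.

    ``n_pairs`` networks are randomly initialized; each is trained twice
    from the identical initialization — once through the coherence
    curriculum 0.7 -> 0.5 -> 0.3 -> 0.1 and once at fixed coherence 0.1 —
    until accuracy at coherence 0.1 reaches ``threshold``.  Returns the
    per-arm iterations-to-criterion and the one-sided paired sign-rank
    p-value for "curriculum is faster".
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2 ** 31, size=(n_pairs, 2))
    spec = NetworkSpec(n_in=2, n_rec=n_rec, n_out=2)
    curriculum_iters, fixed_iters = [], []
    results = []
    for init_seed, train_seed in seeds:
        init = default_initializer(spec, np.random.default_rng(int(init_seed)))
        res_cur = train_to_criterion(
            CURRICULUM_COHERENCES, n_rec=n_rec, threshold=threshold,
            max_iterations=max_iterations, init_seed=int(init_seed),
            train_seed=int(train_seed), initial_weights=init)
        res_fix = train_to_criterion(
            (CURRICULUM_COHERENCES[-1],), n_rec=n_rec, threshold=threshold,
            max_iterations=max_iterations, init_seed=int(init_seed),
            train_seed=int(train_seed), initial_weights=init)
        curriculum_iters.append(res_cur["iterations"])
        fixed_iters.append(res_fix["iterations"])
        results.append((res_cur, res_fix))
    diffs = np.asarray(fixed_iters) - np.asarray(curriculum_iters)
    if np.all(diffs == 0):
        p_value = 1.0
    else:
        p_value = float(stats.wilcoxon(diffs, alternative="greater").pvalue)
    return {
        "curriculum_iterations": curriculum_iters,
        "fixed_iterations": fixed_iters,
        "p_value": p_value,
        "n_pairs": n_pairs,
        "results": results,
    }


def curriculum_final_accuracy(seed: int, *, n_rec: int = 50,
                              threshold: float = 0.9,
                              max_iterations: int = 8000,
                              n_eval: int = 500):
    """Train one network through the coherence curriculum and measure
    accuracy on fresh lowest-coherence trials at the stopping iteration."""
    rng = np.random.default_rng(seed)
    init_seed, train_seed, eval_seed = (int(s) for s in
                                        rng.integers(2 ** 31, size=3))
    res = train_to_criterion(CURRICULUM_COHERENCES, n_rec=n_rec,
                             threshold=threshold,
                             max_iterations=max_iterations,
                             init_seed=init_seed, train_seed=train_seed)
    task = PerceptualDiscrimination(experiment_pd_config(
        (CURRICULUM_COHERENCES[-1],)))
    eval_rng = np.random.default_rng(eval_seed)
    batch = assemble_batch(task, n_eval, eval_rng)
    noise = eval_rng.standard_normal((n_eval, task.T, res["spec"].n_rec))
    _, _, outputs = forward(batch.inputs, res["weights"], res["masks"],
                            res["spec"], noise=noise)
    acc = task.accuracy(outputs, batch)
    return {"accuracy_pct": 100.0 * acc, "n_eval": n_eval,
            "stop_iteration": res["iterations"], "reached": res["reached"],
            "result": res}
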