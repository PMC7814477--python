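"""Closed-loop task shaping (curriculum learning).

A curriculum is an ordered list of task stages with one performance
threshold per stage.  During training, the stage metric (task accuracy by
default, or any user function of the evaluation outputs) is measured at
every evaluation checkpoint; when it reaches the current stage's threshold
the network advances to the next stage.  Reaching the final stage's
threshold completes the curriculum and stops training, so a single-stage
curriculum doubles as a plain stopping criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .task import Batch, Task
from .tasks import PerceptualDiscrimination, PerceptualDiscriminationConfig

__all__ = [
    "CurriculumSpec",
    "CurriculumState",
    "should_advance",
    "advance",
    "default_metric",
    "evaluate_metric",
    "make_coherence_curriculum",
]


@dataclass
class CurriculumSpec:
    """Ordered stages, per-stage thresholds and an optional custom metric.

    ``metric`` has the signature ``metric(outputs, batch, task) -> float``;
    ``None`` means task accuracy.  Thresholds default to 0.9 per stage and
    are compared with "reaches" semantics (advance when ``metric >=
    threshold``).
    """

    stages: Sequence[Task]
    thresholds: Sequence[float] | None = None
    metric: Callable | None = None

    def __post_init__(self):
        self.stages = list(self.stages)
        if len(self.stages) == 0:
            raise ValueError("curriculum needs at least one stage")
        if self.thresholds is None:
            self.thresholds = [0.9] * len(self.stages)
        self.thresholds = [float(t) for t in self.thresholds]
        if len(self.thresholds) != len(self.stages):
            raise ValueError("need exactly one threshold per stage")
        if any(not math.isfinite(t) for t in self.thresholds):
            raise ValueError("thresholds must be finite")


@dataclass
class CurriculumState:
    stage_index: int = 0
    advancement_iterations: list[int] = field(default_factory=list)
    complete: bool = False

    def __post_init__(self):
        it = self.advancement_iterations
        if any(b <= a for a, b in zip(it, it[1:])):
            raise ValueError("advancement_iterations must be strictly increasing")


def should_advance(state: CurriculumState, metric_value: float,
                   spec: CurriculumSpec) -> bool:
    """Whether the current stage's threshold has been reached
    (``metric_value >= threshold``)."""
    if state.complete:
        raise RuntimeError("curriculum already complete")
    return metric_value >= spec.thresholds[state.stage_index]


def advance(state: CurriculumState, spec: CurriculumSpec,
            iteration: int) -> CurriculumState:
    """Move to the next stage, recording the training iteration at which
    the transition fired; completing the last stage marks the curriculum
    complete."""
    if state.complete:
        raise RuntimeError("cannot advance a complete curriculum")
    new_index = state.stage_index + 1
    return CurriculumState(
        stage_index=new_index,
        advancement_iterations=state.advancement_iterations + [int(iteration)],
        complete=new_index == len(spec.stages),
    )


def default_metric(outputs: np.ndarray, batch: Batch, task: Task) -> float:
    """The default stage metric: task accuracy on the evaluation batch."""
    return task.accuracy(outputs, batch)


def evaluate_metric(spec: CurriculumSpec, outputs, batch, task,
                    accuracy_value: float | None = None) -> float:
    """Apply the curriculum's metric (``accuracy_value`` short-circuits the
    default metric when accuracy is already computed)."""
    if spec.metric is None:
        if accuracy_value is not None:
            return float(accuracy_value)
        return default_metric(outputs, batch, task)
    return float(spec.metric(outputs, batch, task))


def make_coherence_curriculum(coherences: Sequence[float],
                              threshold: float = 0.9,
                              base_cfg: PerceptualDiscriminationConfig | None = None,
                              ) -> CurriculumSpec:
    """Perceptual-discrimination curriculum: one stage per coherence (in the
    given order, typically decreasing, e.g. 0.7, 0.5, 0.3, 0.1), uniform
    advancement threshold."""
    coherences = [float(c) for c in coherences]
    if len(coherences) == 0:
        raise ValueError("coherence list must be nonempty")
    if any(not 0.0 <= c <= 1.0 for c in coherences):
        raise ValueError("coherences must lie in [0, 1]")
    if base_cfg is None:
        base_cfg = PerceptualDiscriminationConfig()
    stages = [PerceptualDiscrimination(replace(base_cfg, coherences=(c,)))
              for c in coherences]
    return CurriculumSpec(stages=stages,
                          thresholds=[threshold] * len(coherences))
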