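"""Mean-teacher bookkeeping.

The teacher network is never trained by gradient descent; after every
optimiser step its parameters are moved toward the student's by an
exponential moving average phi_i = eta * phi_{i-1} + (1 - eta) * theta_i.
The student's projector has no counterpart in the teacher and is excluded
from the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, no_grad
from .networks import UNet2D

__all__ = ["EmaState", "ema_update", "teacher_pseudo_labels", "PseudoLabel"]


@dataclass
class EmaState:
    """Matched teacher/student parameter dicts plus the decay eta."""

    decay: float
    teacher_params: dict[str, np.ndarray]
    student_params: dict[str, np.ndarray]
    step: int = 0

    def __post_init__(self):
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("EMA decay must lie in [0, 1]")
        if set(self.teacher_params) != set(self.student_params):
            extra = set(self.teacher_params) ^ set(self.student_params)
            raise ValueError(f"teacher/student parameter sets differ: {sorted(extra)}")


def ema_update(state: EmaState) -> EmaState:
    """One in-place EMA step: phi <- eta*phi + (1-eta)*theta."""
    eta = state.decay
    for name, phi in state.teacher_params.items():
        theta = state.student_params[name]
        if phi.shape != theta.shape:
            raise ValueError(f"shape mismatch for parameter {name}")
        phi *= eta
        phi += (1.0 - eta) * theta
    state.step += 1
    return state


def make_ema_state(teacher: UNet2D, student: UNet2D, decay: float) -> EmaState:
    """Pair up teacher and student parameter arrays, skipping the projector."""
    proj = student.projector_param_names()
    student_params = {k: v.data for k, v in student.named_parameters() if k not in proj}
    teacher_params = {k: v.data for k, v in teacher.named_parameters()}
    return EmaState(decay=decay, teacher_params=teacher_params,
                    student_params=student_params)


@dataclass
class PseudoLabel:
    """Teacher-derived targets: argmax labels gated by max-prob >= tau1."""

    labels: np.ndarray          # (B, H, W) int
    max_prob: np.ndarray        # (B, H, W)
    confident: np.ndarray       # (B, H, W) bool
    probs: np.ndarray = field(repr=False, default=None)  # (B, C, H, W)


def teacher_pseudo_labels(teacher: UNet2D, images, tau1: float) -> PseudoLabel:
    """Run the teacher in inference mode and threshold its confidences.

    No gradient is attached: the returned arrays are plain ndarrays.
    """
    with no_grad():
        out = teacher.forward(images if isinstance(images, Tensor) else Tensor(images))
    probs = out.probs.data
    labels = np.argmax(probs, axis=1)
    max_prob = probs.max(axis=1)
    return PseudoLabel(labels=labels, max_prob=max_prob,
                       confident=max_prob >= tau1, probs=probs)
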