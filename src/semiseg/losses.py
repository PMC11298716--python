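"""Training objectives of the semi-supervised framework.

Four branches contribute to the total objective:

* supervised:      cross-entropy + soft Dice on labeled slices,
* pseudo-label:    confidence-thresholded cross-entropy against argmax
                   targets from a reference (teacher) network,
* consistency:     agreement between predictions from clean and
                   noise-perturbed decoder features,
* reconstruction:  MSE of the variational reconstruction (optional KL).

The three unlabeled-data branches are weighted by a Gaussian ramp-up
delta(t) = exp(-5 (1 - min(t, T)/T)^2) growing from e^-5 to 1 over the
ramp-up period T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor
from .nn import softmax

__all__ = [
    "LossConfig", "LossReport", "supervised_loss", "soft_dice_loss",
    "cross_entropy_loss", "pseudo_label_loss", "perturb_features",
    "consistency_loss", "reconstruction_loss", "rampup_weight", "total_loss",
]

DICE_EPS = 1e-5


@dataclass
class LossConfig:
    """Branch thresholds, weights and the ramp-up schedule length."""

    tau1: float = 0.9               # pseudo-label confidence threshold
    perturb_prob: float = 0.05      # per-element feature-noise probability
    rampup_len: int = 250           # T, iterations; convention: quarter of budget
    w_supervised: float = 1.0
    w_pseudo: float = 1.0
    w_consistency: float = 1.0
    w_reconstruction: float = 1.0
    kl_weight: float = 0.0          # optional KL(N(mu,sigma^2) || N(0,1))

    def __post_init__(self):
        if not 0.0 < self.tau1 <= 1.0:
            raise ValueError("tau1 must lie in (0, 1]")
        if not 0.0 <= self.perturb_prob <= 1.0:
            raise ValueError("perturb_prob must lie in [0, 1]")
        if self.rampup_len < 1:
            raise ValueError("rampup_len must be >= 1")
        for w in (self.w_supervised, self.w_pseudo, self.w_consistency,
                  self.w_reconstruction, self.kl_weight):
            if w < 0:
                raise ValueError("loss weights must be nonnegative")


@dataclass
class LossReport:
    """Scalar values of one training iteration's objective."""

    ls: float = 0.0
    lu: float = 0.0
    lc: float = 0.0
    lrec: float = 0.0
    delta: float = 1.0
    total: float = 0.0
    n_confident: int = 0


def _gather_true_prob(probs: Tensor, labels: np.ndarray) -> Tensor:
    """probs (N, C, H, W), labels (N, H, W) -> per-pixel P[true] (N, H, W)."""
    n, _, h, w = probs.shape
    idx = (np.arange(n)[:, None, None], labels,
           np.arange(h)[None, :, None], np.arange(w)[None, None, :])
    return probs[idx]


def cross_entropy_loss(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean -log P[true class] over every pixel of every slice."""
    probs = as_tensor(probs)
    labels = np.asarray(labels)
    if probs.shape[0] == 0:
        raise ValueError("cross entropy requires at least one slice")
    p_true = _gather_true_prob(probs, labels)
    return -(p_true.log().mean())


def soft_dice_loss(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Soft Dice loss 1 - (2 sum(p*y)+eps)/(sum(p)+sum(y)+eps).

    Computed per slice and per foreground class, averaged over both; the
    background class is excluded, matching common segmentation practice.
    """
    probs = as_tensor(probs)
    labels = np.asarray(labels)
    n, c, _, _ = probs.shape
    losses = []
    for cls in range(1, c):
        y = (labels == cls).astype(probs.data.dtype)  # (N, H, W)
        p = probs[:, cls]                            # (N, H, W)
        inter = (p * y).sum(axis=(1, 2))
        denom = p.sum(axis=(1, 2)) + y.sum(axis=(1, 2))
        losses.append(1.0 - (2.0 * inter + DICE_EPS) / (denom + DICE_EPS))
    stacked = losses[0]
    for extra in losses[1:]:
        stacked = stacked + extra
    return stacked.mean() / float(len(losses))


def supervised_loss(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Cross-entropy over labeled pixels plus soft Dice over labeled slices."""
    probs = as_tensor(probs)
    if probs.shape[0] == 0:
        raise ValueError("supervised loss requires at least one labeled slice")
    return cross_entropy_loss(probs, labels) + soft_dice_loss(probs, np.asarray(labels))


def pseudo_label_loss(probs_student: Tensor, probs_reference: np.ndarray,
                      tau1: float) -> tuple[Tensor, int]:
    """Confidence-gated cross-entropy against argmax pseudo-labels.

    The reference map (teacher, or the student's own detached output)
    supplies both the argmax targets and the confidence gate
    max_c P >= tau1.  The sum is normalised by the full pixel count
    H*W*N2 regardless of how many pixels pass the gate, so padding a
    batch with unconfident pixels strictly lowers the loss.  Ties in the
    argmax resolve to the lowest class index.
    """
    probs_student = as_tensor(probs_student)
    ref = np.asarray(probs_reference if not isinstance(probs_reference, Tensor)
                     else probs_reference.data)
    if probs_student.shape != ref.shape:
        raise ValueError("student and reference probability maps differ in shape")
    pseudo = np.argmax(ref, axis=1)                      # (N, H, W)
    confident = (ref.max(axis=1) >= tau1).astype(probs_student.data.dtype)
    n_conf = int(confident.sum())
    if n_conf == 0:
        return as_tensor(0.0), 0
    p_true = _gather_true_prob(probs_student, pseudo)
    # unconfident entries are replaced by 1 so their log vanishes exactly
    p_safe = p_true * confident + (1.0 - confident)
    return -(p_safe.log().mean()), n_conf


def perturb_features(features, perturb_prob: float, rng: np.random.Generator):
    """Add N(0,1) noise to each element independently with probability p.

    The selection mask is drawn first, then the noise values; unselected
    elements are bit-identical to the input.  Accepts a Tensor (gradients
    pass through unchanged — the noise is constant) or a plain array.
    """
    if not 0.0 <= perturb_prob <= 1.0:
        raise ValueError("perturb_prob must lie in [0, 1]")
    shape = features.shape
    mask = rng.random(shape) < perturb_prob
    noise = rng.standard_normal(shape) * mask
    if isinstance(features, Tensor):
        return features + noise.astype(features.data.dtype, copy=False)
    return np.asarray(features) + noise


def consistency_loss(model_head, features: Tensor, perturb_prob: float,
                     rng: np.random.Generator, mode: str = "soft"):
    """Penalty for prediction drift under feature perturbation.

    soft (default, differentiable): mean squared difference between the
    softmax outputs of h(I) and h(g(I)).  hard (evaluation only): mean
    squared difference of the two argmax label maps, returned as a plain
    float — it cannot be backpropagated.
    """
    if mode not in ("soft", "hard"):
        raise ValueError(f"unknown consistency mode {mode!r}")
    features = as_tensor(features)
    perturbed = perturb_features(features, perturb_prob, rng)
    logits_clean = model_head(features)
    logits_pert = model_head(perturbed)
    if mode == "hard":
        y0 = np.argmax(logits_clean.data, axis=1)
        y1 = np.argmax(logits_pert.data, axis=1)
        return float(np.mean((y0 - y1) ** 2))
    p0 = softmax(logits_clean)
    p1 = softmax(logits_pert)
    return ((p0 - p1) ** 2).mean()


def reconstruction_loss(reconstruction: Tensor, images: np.ndarray,
                        mu: Tensor | None = None, log_var: Tensor | None = None,
                        kl_weight: float = 0.0) -> Tensor:
    """MSE between reconstruction and input, plus optional KL to N(0, I)."""
    reconstruction = as_tensor(reconstruction)
    images = images.data if isinstance(images, Tensor) else np.asarray(images)
    if reconstruction.shape != images.shape:
        raise ValueError("reconstruction and image shapes differ")
    loss = ((reconstruction - images) ** 2).mean()
    if kl_weight > 0.0:
        if mu is None or log_var is None:
            raise ValueError("kl_weight > 0 requires mu and log_var")
        kl_per_sample = (-0.5) * (1.0 + log_var - mu**2 - log_var.exp()).sum(axis=1)
        loss = loss + kl_weight * kl_per_sample.mean()
    return loss


def rampup_weight(t: float, rampup_len: int) -> float:
    """Gaussian ramp-up delta = exp(-5 (1 - min(t, T)/T)^2), in [e^-5, 1]."""
    if rampup_len <= 0:
        raise ValueError("rampup_len must be positive")
    if t < 0:
        raise ValueError("t must be nonnegative")
    frac = min(float(t), float(rampup_len)) / float(rampup_len)
    return math.exp(-5.0 * (1.0 - frac) ** 2)


def total_loss(components: dict, config: LossConfig, t: float) -> tuple[Tensor, LossReport]:
    """Combine branch losses: w_s*Ls + delta(t) * (w_u*Lu + w_c*Lc + w_r*Lrec).

    ``components`` maps branch names ("supervised", "pseudo", "consistency",
    "reconstruction") to scalar Tensors; absent branches contribute zero.
    Returns the differentiable total and a float-valued report.
    """
    delta = rampup_weight(t, config.rampup_len)
    zero = as_tensor(0.0)
    ls = components.get("supervised", zero)
    lu = components.get("pseudo", zero)
    lc = components.get("consistency", zero)
    lrec = components.get("reconstruction", zero)
    total = (config.w_supervised * ls
             + delta * (config.w_pseudo * lu
                        + config.w_consistency * lc
                        + config.w_reconstruction * lrec))
    report = LossReport(ls=float(ls), lu=float(lu), lc=float(lc),
                        lrec=float(lrec), delta=delta, total=float(total),
                        n_confident=int(components.get("n_confident", 0)))
    return total, report
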