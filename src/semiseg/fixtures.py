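"""Deterministic hand-sized fixtures with independently computed expectations.

Each fixture bundles small arrays with expected values that are either
closed-form arithmetic or produced at build time by the naive brute-force
oracles defined below.  The oracles are deliberately simple scalar loops,
independent of the vectorised implementations they are used to check.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Fixture", "build_fixture", "available_fixtures",
           "oracle_dice", "oracle_iou", "oracle_boundary",
           "oracle_surface_distances", "oracle_supervised_loss",
           "oracle_pseudo_loss"]


# ---------------------------------------------------------------------------
# Naive oracles (scalar loops, auditable by eye)
# ---------------------------------------------------------------------------

def oracle_dice(m1, m2) -> float:
    inter = a = b = 0
    for x, y in zip(np.asarray(m1).ravel(), np.asarray(m2).ravel()):
        a += bool(x)
        b += bool(y)
        inter += bool(x) and bool(y)
    return 1.0 if a + b == 0 else 2.0 * inter / (a + b)


def oracle_iou(m1, m2) -> float:
    inter = union = 0
    for x, y in zip(np.asarray(m1).ravel(), np.asarray(m2).ravel()):
        union += bool(x) or bool(y)
        inter += bool(x) and bool(y)
    return 1.0 if union == 0 else inter / union


def oracle_boundary(mask) -> list[tuple[int, ...]]:
    """Foreground cells with a face-neighbour outside the foreground."""
    mask = np.asarray(mask).astype(bool)
    pts = []
    for idx in np.ndindex(mask.shape):
        if not mask[idx]:
            continue
        on_boundary = False
        for ax in range(mask.ndim):
            for step in (-1, 1):
                nb = list(idx)
                nb[ax] += step
                if not (0 <= nb[ax] < mask.shape[ax]) or not mask[tuple(nb)]:
                    on_boundary = True
        if on_boundary:
            pts.append(idx)
    return pts


def oracle_surface_distances(m1, m2) -> tuple[list[float], list[float]]:
    """All-pairs nearest boundary distances in both directions."""
    b1 = oracle_boundary(m1)
    b2 = oracle_boundary(m2)
    d12 = [min(math.dist(p, q) for q in b2) for p in b1]
    d21 = [min(math.dist(q, p) for p in b1) for q in b2]
    return d12, d21


def oracle_supervised_loss(probs, labels, eps: float = 1e-5) -> float:
    """Scalar-loop CE over pixels plus per-slice soft Dice over classes."""
    probs = np.asarray(probs)   # (N, C, H, W)
    labels = np.asarray(labels)
    n, c, h, w = probs.shape
    ce = 0.0
    for s in range(n):
        for i in range(h):
            for j in range(w):
                ce += -math.log(probs[s, labels[s, i, j], i, j])
    ce /= n * h * w
    dice = 0.0
    for s in range(n):
        per_class = []
        for cls in range(1, c):
            inter = psum = ysum = 0.0
            for i in range(h):
                for j in range(w):
                    y = 1.0 if labels[s, i, j] == cls else 0.0
                    inter += probs[s, cls, i, j] * y
                    psum += probs[s, cls, i, j]
                    ysum += y
            per_class.append(1.0 - (2.0 * inter + eps) / (psum + ysum + eps))
        dice += sum(per_class) / len(per_class)
    return ce + dice / n


def oracle_pseudo_loss(probs_student, probs_ref, tau1) -> tuple[float, int]:
    """Scalar-loop thresholded CE with the unconditional HW*N normaliser."""
    ps = np.asarray(probs_student)
    pr = np.asarray(probs_ref)
    n, c, h, w = ps.shape
    loss, n_conf = 0.0, 0
    for s in range(n):
        for i in range(h):
            for j in range(w):
                conf = max(pr[s, cls, i, j] for cls in range(c))
                if conf >= tau1:
                    target = int(np.argmax(pr[s, :, i, j]))
                    loss += -math.log(ps[s, target, i, j])
                    n_conf += 1
    return loss / (n * h * w), n_conf


# ---------------------------------------------------------------------------
# Fixture registry
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    name: str
    payload: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)
    tolerance: float = 1e-9
    provenance: str = ""

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for key in sorted(self.payload):
            h.update(key.encode())
            h.update(np.ascontiguousarray(self.payload[key]).tobytes())
        return h.hexdigest()[:16]


def _random_probs(rng, n, c, h, w):
    raw = rng.random((n, c, h, w)) + 0.05
    return raw / raw.sum(axis=1, keepdims=True)


def _random_blob(rng, size=32):
    mask = np.zeros((size, size), dtype=bool)
    cy, cx = rng.uniform(8, size - 8, 2)
    ry, rx = rng.uniform(3, 7, 2)
    yy, xx = np.ogrid[:size, :size]
    mask |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return mask


def _fx_dice_half_overlap() -> Fixture:
    m1 = np.zeros((4, 4), bool)
    m2 = np.zeros((4, 4), bool)
    m1[0, :4] = True            # |M1| = 4
    m2[0, 2:] = True            # overlap 2
    m2[1, 2:] = True            # |M2| = 4
    return Fixture("dice_half_overlap", {"m1": m1, "m2": m2},
                   {"dice": 0.5, "iou": oracle_iou(m1, m2)},
                   provenance="TRIVIAL: 2*2/(4+4)")


def _fx_eq2_single_pixel() -> Fixture:
    probs = np.array([0.95, 0.05]).reshape(1, 2, 1, 1)
    return Fixture("eq2_single_pixel",
                   {"probs": probs, "tau1": np.array(0.9)},
                   {"loss": -math.log(0.95), "n_confident": 1},
                   provenance="TRIVIAL: single-pixel closed form")


def _fx_hd95_random_32() -> Fixture:
    rng = np.random.default_rng(1234)
    m1 = _random_blob(rng)
    m2 = _random_blob(rng)
    d12, d21 = oracle_surface_distances(m1, m2)
    hd = max(np.percentile(d12, 95), np.percentile(d21, 95))
    a = (sum(d12) + sum(d21)) / (len(d12) + len(d21))
    return Fixture("hd95_random_32", {"m1": m1, "m2": m2},
                   {"hd95": float(hd), "asd": float(a)},
                   provenance="DERIVED: all-pairs boundary-distance oracle")


def _fx_eq1_random_4x4() -> Fixture:
    rng = np.random.default_rng(7)
    probs = _random_probs(rng, 2, 3, 4, 4)
    labels = rng.integers(0, 3, size=(2, 4, 4))
    return Fixture("eq1_random_4x4", {"probs": probs, "labels": labels},
                   {"loss": oracle_supervised_loss(probs, labels)},
                   provenance="DERIVED: scalar-loop CE+Dice oracle")


def _fx_rampup_points() -> Fixture:
    return Fixture("rampup_points", {"t": np.array([0.0, 0.5, 1.0, 2.0])},
                   {"delta": [math.exp(-5.0), math.exp(-1.25), 1.0, 1.0]},
                   provenance="TRIVIAL: direct evaluation at fractions of T")


_REGISTRY = {
    "dice_half_overlap": _fx_dice_half_overlap,
    "eq2_single_pixel": _fx_eq2_single_pixel,
    "hd95_random_32": _fx_hd95_random_32,
    "eq1_random_4x4": _fx_eq1_random_4x4,
    "rampup_points": _fx_rampup_points,
}


def available_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def build_fixture(name: str) -> Fixture:
    """Build a registered fixture; derived expectations come from the
    brute-force oracles at build time, never from hard-coded numbers."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {available_fixtures()}") from None
    return builder()
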