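"""Dataset handling: synthetic corpus generation, preprocessing,
augmentation, two-stream batch sampling and PNG/NIfTI round-trips.

The synthetic generator emulates the structure of semi-supervised cardiac
MRI corpora: each *subject* is a noisy grayscale image (or volume) whose
foreground classes are randomly placed, non-overlapping ellipses with a
per-subject intensity offset; the labeled/unlabeled split is made at the
subject level, so no subject ever contributes both labeled and unlabeled
slices.  Ground truth for unlabeled subjects is retained internally for
held-out evaluation but is not exposed through ``Subject.mask``.

Arrays are indexed (depth, row, col) for volumes and (row, col) for
slices, 0-based; physical voxel spacing rides alongside.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v2 as imageio
import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "Subject", "SampleBatch", "SyntheticConfig", "generate_synthetic_dataset",
    "normalize_image", "random_crop", "augment", "two_stream_batches",
    "load_dataset", "write_mask", "save_dataset",
]


class Subject:
    """One patient: an intensity volume plus (when labeled) its mask.

    ``mask`` is None for unlabeled subjects even when a ground-truth mask
    exists (synthetic corpora keep it privately for evaluation via
    ``ground_truth``).
    """

    def __init__(self, id: str, volume: np.ndarray, mask: np.ndarray | None,
                 labeled: bool, spacing=None):
        volume = np.asarray(volume, dtype=float)
        if mask is not None:
            mask = np.asarray(mask)
            if not np.issubdtype(mask.dtype, np.integer):
                raise ValueError("mask must be an integer array")
            if mask.shape != volume.shape:
                raise ValueError("volume and mask shapes differ")
        if labeled and mask is None:
            raise ValueError("labeled subject requires a mask")
        self.id = str(id)
        self.volume = volume
        self.labeled = bool(labeled)
        self.spacing = tuple(spacing) if spacing is not None else (1.0,) * volume.ndim
        self._mask = mask

    @property
    def mask(self) -> np.ndarray | None:
        """Ground-truth mask, visible only for labeled subjects."""
        return self._mask if self.labeled else None

    @property
    def ground_truth(self) -> np.ndarray | None:
        """Mask regardless of labeled status — for evaluation only."""
        return self._mask

    def __repr__(self):
        return (f"Subject({self.id!r}, shape={self.volume.shape}, "
                f"labeled={self.labeled})")


@dataclass
class SampleBatch:
    """Training unit: stacked image patches with per-member labeled flags."""

    images: np.ndarray            # (B, 1, [D,] H, W)
    masks: np.ndarray | None      # (N1, [D,] H, W) labels of labeled members
    labeled_mask: np.ndarray      # (B,) bool, labeled members come first

    def __post_init__(self):
        self.labeled_mask = np.asarray(self.labeled_mask, dtype=bool)
        if self.images.shape[0] != self.labeled_mask.size:
            raise ValueError("images and labeled_mask disagree on batch size")
        n1 = int(self.labeled_mask.sum())
        if n1 and (self.masks is None or self.masks.shape[0] != n1):
            raise ValueError("labeled members require matching masks")
        if n1 and not self.labeled_mask[:n1].all():
            raise ValueError("labeled members must precede unlabeled members")

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_mask.sum())

    @property
    def n_unlabeled(self) -> int:
        return int((~self.labeled_mask).sum())


@dataclass
class SyntheticConfig:
    """Stated world of the synthetic corpus.

    Defaults emulate a desk-scale analogue of cardiac MRI data: small
    foreground fraction, per-subject contrast variation, moderate noise.
    """

    n_subjects: int = 100
    shape: tuple[int, ...] = (64, 64)
    n_classes: int = 2
    labeled_proportion: float = 0.1
    noise_sd: float = 0.4
    min_radius: int = 5
    max_radius: int = 14
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.n_classes < 2:
            raise ValueError("need at least background + one foreground class")
        if not 0.0 < self.labeled_proportion <= 1.0:
            raise ValueError("labeled_proportion must lie in (0, 1]")
        if self.labeled_proportion * self.n_subjects < 1.0:
            raise ValueError("labeled_proportion * n_subjects must be >= 1")
        if self.min_radius > self.max_radius:
            raise ValueError("min_radius must not exceed max_radius")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _place_ellipse(shape, rng, min_r, max_r, occupied, tries: int = 200):
    """Boolean rotated ellipse/ellipsoid mask avoiding occupied voxels.

    The in-plane axes are rotated by a random angle so structure
    orientation varies across subjects.
    """
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    for _ in range(tries):
        radii = [rng.uniform(min_r, min(max_r, (s - 1) / 2)) for s in shape]
        center = [rng.uniform(r, s - 1 - r) for r, s in zip(radii, shape)]
        theta = rng.uniform(0.0, np.pi)
        rel = [g - c for g, c in zip(grids, center)]
        # rotate the trailing (row, col) plane
        u = rel[-2] * np.cos(theta) + rel[-1] * np.sin(theta)
        v = -rel[-2] * np.sin(theta) + rel[-1] * np.cos(theta)
        quad = (u / radii[-2]) ** 2 + (v / radii[-1]) ** 2
        for ax in range(len(shape) - 2):
            quad = quad + (rel[ax] / radii[ax]) ** 2
        ell = quad <= 1.0
        if ell.any() and not (ell & occupied).any():
            return ell
    raise RuntimeError("could not place a non-overlapping structure; "
                       "reduce n_classes or max_radius")


def _correlated_noise(shape, rng, sd):
    """White (thermal) noise plus a weaker smooth bias-field-like component.

    The smooth field has 0.4 the white component's amplitude, roughly the
    relative strength of coil-inhomogeneity artifacts in MR images; the
    mixture is scaled so the total sd equals ``sd``.
    """
    from scipy.ndimage import gaussian_filter
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 8.0)
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    return sd * (white + 0.4 * smooth) / np.sqrt(1.16)


def generate_synthetic_dataset(config: SyntheticConfig) -> list[Subject]:
    """Deterministically synthesise a labeled/unlabeled subject corpus.

    Each foreground class occupies one randomly placed and oriented
    ellipse with a constant per-subject intensity offset drawn from
    U(0.4, 1.2) over a zero background.  Zero-mean noise (white plus a
    weaker smooth bias-field-like component) is added everywhere, with a
    per-subject amplitude of U(0.5, 1.5) x ``noise_sd`` emulating
    scanner/protocol variation.  Exactly round(p * n_subjects) subjects
    (at least one) are labeled, chosen by a seeded permutation.
    """
    rng = np.random.default_rng(config.seed)
    n_labeled = max(1, int(math.floor(config.labeled_proportion
                                      * config.n_subjects + 0.5)))
    order = rng.permutation(config.n_subjects)
    labeled_set = set(int(i) for i in order[:n_labeled])

    subjects = []
    for i in range(config.n_subjects):
        volume = np.zeros(config.shape, dtype=float)
        mask = np.zeros(config.shape, dtype=np.int64)
        occupied = np.zeros(config.shape, dtype=bool)
        for cls in range(1, config.n_classes):
            ell = _place_ellipse(config.shape, rng, config.min_radius,
                                 config.max_radius, occupied)
            offset = rng.uniform(0.4, 1.2)
            volume[ell] = offset
            mask[ell] = cls
            occupied |= ell
        if config.noise_sd > 0:
            # per-subject noise amplitude emulates scanner/protocol variation
            subject_sd = config.noise_sd * rng.uniform(0.5, 1.5)
            volume = volume + _correlated_noise(config.shape, rng, subject_sd)
        labeled = i in labeled_set
        subjects.append(Subject(id=f"subj{i:03d}", volume=volume, mask=mask,
                                labeled=labeled))
    return subjects


def normalize_image(volume: np.ndarray) -> np.ndarray:
    """Zero-mean unit-sd intensity normalisation (population sd).

    Constant images (sd < 1e-8) map to all-zeros rather than dividing by
    a vanishing sd.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.size == 0:
        raise ValueError("cannot normalize an empty volume")
    sd = volume.std()
    if sd < 1e-8:
        return np.zeros_like(volume)
    return (volume - volume.mean()) / sd


def random_crop(volume: np.ndarray, mask: np.ndarray | None,
                patch_size, rng: np.random.Generator):
    """Uniformly placed axis-aligned crop, identical offsets for the mask."""
    volume = np.asarray(volume)
    patch_size = tuple(int(p) for p in patch_size)
    if len(patch_size) != volume.ndim:
        raise ValueError("patch_size rank must match volume rank")
    if any(p > s for p, s in zip(patch_size, volume.shape)):
        raise ValueError(f"patch {patch_size} exceeds volume {volume.shape}")
    offsets = tuple(int(rng.integers(0, s - p + 1))
                    for p, s in zip(patch_size, volume.shape))
    sl = tuple(slice(o, o + p) for o, p in zip(offsets, patch_size))
    return volume[sl].copy(), (None if mask is None else mask[sl].copy())


def augment(image: np.ndarray, mask: np.ndarray | None, ops,
            rng: np.random.Generator, free_angle: bool = False):
    """Random rotation/flip (applied to image and mask alike) and intensity
    jitter (image only).

    Rotations default to 90-degree multiples in the in-plane axes so masks
    stay exact; ``free_angle=True`` enables arbitrary-angle rotation with
    nearest-neighbour mask resampling.
    """
    ops = set(ops)
    unknown = ops - {"rotate", "flip", "jitter"}
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    image = np.asarray(image, dtype=float).copy()
    mask = None if mask is None else np.asarray(mask).copy()
    axes = (image.ndim - 2, image.ndim - 1)  # in-plane
    if "rotate" in ops:
        if free_angle:
            from scipy.ndimage import rotate as nd_rotate
            angle = float(rng.uniform(0.0, 360.0))
            image = nd_rotate(image, angle, axes=axes, reshape=False, order=1)
            if mask is not None:
                mask = nd_rotate(mask, angle, axes=axes, reshape=False, order=0)
        else:
            k = int(rng.integers(0, 4))
            image = np.rot90(image, k, axes=axes)
            if mask is not None:
                mask = np.rot90(mask, k, axes=axes)
    if "flip" in ops:
        for ax in range(image.ndim):
            if rng.random() < 0.5:
                image = np.flip(image, axis=ax)
                if mask is not None:
                    mask = np.flip(mask, axis=ax)
    if "jitter" in ops:
        scale = float(rng.uniform(0.9, 1.1))
        shift = float(rng.uniform(-0.1, 0.1))
        image = image * scale + shift
    return np.ascontiguousarray(image), (
        None if mask is None else np.ascontiguousarray(mask))


def two_stream_batches(labeled_ids, unlabeled_ids, batch_size: int,
                       n_labeled_per_batch: int, rng: np.random.Generator,
                       mode: str = "two_stream", epochs: int | None = None):
    """Yield (labeled_batch, unlabeled_batch) id tuples.

    two_stream mode: every batch holds exactly ``n_labeled_per_batch``
    labeled ids; unlabeled ids are drawn without replacement within an
    epoch (reshuffled between epochs), labeled ids cycle through
    reshuffled permutations of the labeled pool.

    duplication mode: the labeled pool is tiled to the unlabeled pool's
    length, both pools are concatenated and shuffled, and consecutive
    ``batch_size`` slices are emitted (labeled counts then vary batch to
    batch).

    ``epochs=None`` yields indefinitely.
    """
    labeled_ids = list(labeled_ids)
    unlabeled_ids = list(unlabeled_ids)
    if not labeled_ids:
        raise ValueError("labeled pool is empty")
    if mode == "two_stream":
        if not 1 <= n_labeled_per_batch <= batch_size - 1:
            raise ValueError("n_labeled_per_batch must lie in [1, batch_size-1]")
        if not unlabeled_ids:
            raise ValueError("two-stream mode requires unlabeled data")
        n_unl = batch_size - n_labeled_per_batch

        def lab_cycle():
            while True:
                for i in rng.permutation(len(labeled_ids)):
                    yield labeled_ids[i]

        lab_iter = lab_cycle()
        epoch = 0
        while epochs is None or epoch < epochs:
            perm = rng.permutation(len(unlabeled_ids))
            for start in range(0, len(perm) - n_unl + 1, n_unl):
                unl = [unlabeled_ids[i] for i in perm[start:start + n_unl]]
                lab = [next(lab_iter) for _ in range(n_labeled_per_batch)]
                yield lab, unl
            epoch += 1
    elif mode == "duplication":
        reps = math.ceil(len(unlabeled_ids) / len(labeled_ids)) if unlabeled_ids else 1
        tiled = (labeled_ids * reps)[: max(len(unlabeled_ids), len(labeled_ids))]
        labeled_set = set(labeled_ids)
        pool = tiled + unlabeled_ids
        epoch = 0
        while epochs is None or epoch < epochs:
            perm = rng.permutation(len(pool))
            for start in range(0, len(perm) - batch_size + 1, batch_size):
                chunk = [pool[i] for i in perm[start:start + batch_size]]
                lab = [s for s in chunk if s in labeled_set]
                unl = [s for s in chunk if s not in labeled_set]
                yield lab, unl
            epoch += 1
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")


# ---------------------------------------------------------------------------
# File I/O: PNG slice stacks, NIfTI volumes, YAML manifests
# ---------------------------------------------------------------------------

_SLICE_RE = re.compile(r"(\d+)\.png$")


def _affine(spacing) -> np.ndarray:
    """4x4 NIfTI affine with voxel sizes on the diagonal (2-D or 3-D)."""
    affine = np.eye(4)
    for i, s in enumerate(spacing):
        affine[i, i] = s
    return affine


def _read_png_stack(directory: Path) -> np.ndarray:
    files = sorted(directory.glob("*.png"),
                   key=lambda p: int(_SLICE_RE.search(p.name).group(1)))
    if not files:
        raise FileNotFoundError(f"no PNG slices under {directory}")
    slices = [np.asarray(imageio.imread(f)) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"mixed slice shapes in {directory}: {shapes}")
    return np.stack(slices, axis=0)


def _write_png_stack(directory: Path, volume: np.ndarray) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    vol = np.asarray(volume)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.min() < 0 or vol.max() > 255:
        raise ValueError("png_stack stores 8-bit values in [0, 255]")
    for i, sl in enumerate(vol):
        imageio.imwrite(directory / f"{i:04d}.png", sl.astype(np.uint8))


def write_mask(path, mask: np.ndarray, format: str = "png_stack",
               spacing=None) -> None:
    """Write an integer mask as a PNG slice stack or a NIfTI volume.

    png_stack stores class indices directly as 8-bit values (<= 256
    classes); the round trip back through :func:`load_dataset` helpers is
    lossless.
    """
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must be integer-valued")
    path = Path(path)
    if format == "png_stack":
        if mask.min() < 0 or mask.max() > 255:
            raise ValueError("png_stack supports class indices 0..255")
        _write_png_stack(path, mask)
    elif format == "nifti":
        spacing = (1.0,) * mask.ndim if spacing is None else tuple(spacing)
        nib.save(nib.Nifti1Image(mask.astype(np.int16), _affine(spacing)), str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_mask(path, format: str = "png_stack") -> np.ndarray:
    path = Path(path)
    if format == "png_stack":
        return _read_png_stack(path).astype(np.int64)
    if format == "nifti":
        img = nib.load(str(path))
        return np.asarray(img.dataobj).astype(np.int64)
    raise ValueError(f"unknown format {format!r}")


def save_dataset(subjects: list[Subject], out_dir, format: str = "nifti") -> Path:
    """Write subjects plus a YAML manifest; returns the manifest path.

    Intensity volumes are stored as NIfTI even in png_stack mode (PNG is
    8-bit; synthetic intensities are real-valued), masks in the requested
    format.  Unlabeled subjects' masks are not written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in subjects:
        img_path = out_dir / f"{s.id}_img.nii.gz"
        nib.save(nib.Nifti1Image(s.volume.astype(np.float32), _affine(s.spacing)),
                 str(img_path))
        entry = {"id": s.id, "labeled": s.labeled, "image": img_path.name,
                 "spacing": list(s.spacing), "mask": None}
        if s.labeled:
            if format == "png_stack":
                mpath = out_dir / f"{s.id}_mask"
            else:
                mpath = out_dir / f"{s.id}_mask.nii.gz"
            write_mask(mpath, s.mask, format=format, spacing=s.spacing)
            entry["mask"] = mpath.name
            entry["mask_format"] = format
        entries.append(entry)
    manifest = out_dir / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"subjects": entries}, sort_keys=False))
    return manifest


def load_dataset(path) -> list[Subject]:
    """Load a manifest-described dataset written by :func:`save_dataset`."""
    path = Path(path)
    manifest = path / "manifest.yaml" if path.is_dir() else path
    root = manifest.parent
    doc = yaml.safe_load(manifest.read_text())
    subjects = []
    for e in doc["subjects"]:
        img = nib.load(str(root / e["image"]))
        volume = np.asarray(img.dataobj, dtype=float)
        spacing = tuple(e.get("spacing") or img.header.get_zooms()[: volume.ndim])
        mask = None
        if e.get("mask"):
            mask = read_mask(root / e["mask"], format=e.get("mask_format", "nifti"))
        subjects.append(Subject(id=e["id"], volume=volume, mask=mask,
                                labeled=bool(e["labeled"]), spacing=spacing))
    return subjects
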