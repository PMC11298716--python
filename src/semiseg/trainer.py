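"""Training orchestration: the semi-supervised loop, evaluation, ablations.

One iteration of the full framework:

1. sample a two-stream batch (fixed labeled/unlabeled mix),
2. student forward pass,
3. supervised CE+Dice loss on the labeled members,
4. confidence-thresholded pseudo-label loss on the unlabeled members,
   with targets from the EMA teacher (or the student's own detached
   predictions when the teacher is disabled),
5. consistency loss between predictions from clean and noise-perturbed
   decoder features,
6. variational reconstruction loss on all members,
7. ramp-up-weighted total, Adam step under cosine-annealed lr,
8. EMA update of the teacher.

Every stochastic choice draws from a named substream of the root seed, so
disabling a branch never shifts the draws of the remaining ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autograd import Tensor
from .data import (SampleBatch, Subject, SyntheticConfig, augment,
                   generate_synthetic_dataset, normalize_image, random_crop,
                   two_stream_batches)
from .losses import (LossConfig, consistency_loss, pseudo_label_loss,
                     reconstruction_loss, supervised_loss, total_loss)
from .metrics import evaluate_volume
from .networks import UNet2D
from .optim import Adam, cosine_lr
from .teacher_student import ema_update, make_ema_state, teacher_pseudo_labels

__all__ = ["ExperimentConfig", "TrainResult", "train", "evaluate",
           "run_ablation", "named_rng", "assemble_batch", "ABLATION_ARMS"]

_STREAMS = ("data", "batch", "augment", "perturb", "epsilon", "init")


def named_rng(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named source of randomness."""
    if name not in _STREAMS:
        raise ValueError(f"unknown stream {name!r}; expected one of {_STREAMS}")
    child = np.random.SeedSequence(seed).spawn(len(_STREAMS))[_STREAMS.index(name)]
    return np.random.default_rng(child)


@dataclass
class ExperimentConfig:
    """Everything one training run needs; defaults are the desk-scale profile."""

    data: SyntheticConfig = field(default_factory=SyntheticConfig)
    n_test_subjects: int = 20
    # model
    base_channels: int = 8
    depth: int = 1
    latent_dim: int = 16
    # optimisation
    lr: float = 5e-4
    weight_decay: float = 1e-4
    lr_floor: float = 1e-7
    iterations: int = 300
    batch_size: int = 8
    n_labeled_per_batch: int = 4
    sampler_mode: str = "two_stream"
    patch_size: tuple[int, ...] | None = None
    augment_ops: tuple[str, ...] = ("rotate", "flip")
    # loss / branches
    loss: LossConfig | None = None
    ema_decay: float = 0.95
    use_pseudo: bool = True
    use_consistency: bool = True
    use_reconstruction: bool = True
    use_teacher_student: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.loss is None:
            # ramp-up period: one quarter of the training budget
            self.loss = LossConfig(rampup_len=max(1, self.iterations // 4))
        if self.sampler_mode not in ("two_stream", "duplication"):
            raise ValueError(f"unknown sampler mode {self.sampler_mode!r}")

    @property
    def semi_supervised(self) -> bool:
        return self.use_pseudo or self.use_consistency or self.use_reconstruction


@dataclass
class TrainResult:
    student: UNet2D
    teacher: UNet2D | None
    log: pd.DataFrame
    config: ExperimentConfig
    train_subjects: list[Subject]
    split_hash: str


def split_hash(subjects: list[Subject]) -> str:
    """Digest of the labeled/unlabeled partition, for ablation bookkeeping."""
    text = ";".join(f"{s.id}:{int(s.labeled)}" for s in sorted(subjects, key=lambda s: s.id))
    return hashlib.sha1(text.encode()).hexdigest()[:16]


def assemble_batch(by_id: dict[str, Subject], labeled_ids, unlabeled_ids,
                   augment_ops, aug_rng, patch_size=None) -> SampleBatch:
    """Normalise, optionally crop, and augment one batch of 2-D subjects."""
    images, masks, flags = [], [], []
    for sid in list(labeled_ids) + list(unlabeled_ids):
        subj = by_id[sid]
        img = normalize_image(subj.volume)
        msk = subj.mask
        if patch_size is not None:
            img, msk = random_crop(img, msk, patch_size, aug_rng)
        if augment_ops:
            img, msk = augment(img, msk, augment_ops, aug_rng)
        images.append(img)
        flags.append(subj.labeled)
        if subj.labeled:
            masks.append(msk)
    images = np.stack(images)[:, None].astype(np.float32)  # (B, 1, H, W)
    masks = np.stack(masks).astype(np.int64) if masks else None
    return SampleBatch(images=images, masks=masks,
                       labeled_mask=np.array(flags, dtype=bool))


def _generate_corpus(config: ExperimentConfig):
    train_subjects = generate_synthetic_dataset(config.data)
    test_cfg = replace(config.data, n_subjects=config.n_test_subjects,
                       labeled_proportion=1.0,
                       seed=(config.data.seed + 10007) % (2**31))
    test_subjects = generate_synthetic_dataset(test_cfg)
    return train_subjects, test_subjects


def train(config: ExperimentConfig,
          subjects: list[Subject] | None = None) -> TrainResult:
    """Run one semi-supervised (or ablated) training job."""
    if subjects is None:
        subjects = generate_synthetic_dataset(config.data)
    labeled = [s for s in subjects if s.labeled]
    unlabeled = [s for s in subjects if not s.labeled]
    if not labeled:
        raise ValueError("training requires at least one labeled subject")
    by_id = {s.id: s for s in subjects}

    init_rng = named_rng(config.seed, "init")
    shape = labeled[0].volume.shape
    student = UNet2D(in_channels=1, n_classes=config.data.n_classes,
                     base_channels=config.base_channels, depth=config.depth,
                     latent_dim=config.latent_dim,
                     input_size=config.patch_size or shape,
                     with_projector=True, rng=init_rng)
    teacher = student.make_teacher() if config.use_teacher_student else None
    ema = (make_ema_state(teacher, student, config.ema_decay)
           if teacher is not None else None)

    batch_rng = named_rng(config.seed, "batch")
    aug_rng = named_rng(config.seed, "augment")
    perturb_rng = named_rng(config.seed, "perturb")
    eps_rng = named_rng(config.seed, "epsilon")

    lab_ids = [s.id for s in labeled]
    unl_ids = [s.id for s in unlabeled]
    use_unlabeled = config.semi_supervised and unl_ids
    if use_unlabeled:
        sampler = two_stream_batches(lab_ids, unl_ids, config.batch_size,
                                     config.n_labeled_per_batch, batch_rng,
                                     mode=config.sampler_mode)
    else:
        def supervised_sampler():
            while True:
                perm = batch_rng.permutation(len(lab_ids))
                n = min(config.batch_size, len(lab_ids))
                for start in range(0, len(perm) - n + 1, n):
                    yield [lab_ids[i] for i in perm[start:start + n]], []
        sampler = supervised_sampler()

    optimizer = Adam(student.parameters(), lr=config.lr,
                     weight_decay=config.weight_decay)
    rows = []
    for it in range(config.iterations):
        lab_batch, unl_batch = next(sampler)
        batch = assemble_batch(by_id, lab_batch, unl_batch, config.augment_ops,
                               aug_rng, config.patch_size)
        n1 = batch.n_labeled
        outs = student(Tensor(batch.images))

        components: dict = {}
        if n1:  # duplication-mode batches may occasionally hold no labeled member
            components["supervised"] = supervised_loss(outs.probs[:n1], batch.masks)

        if config.use_pseudo and batch.n_unlabeled:
            unl_imgs = batch.images[n1:]
            if teacher is not None:
                ref = teacher_pseudo_labels(teacher, unl_imgs, config.loss.tau1).probs
            else:
                ref = outs.probs.data[n1:]
            lu, n_conf = pseudo_label_loss(outs.probs[n1:], ref, config.loss.tau1)
            components["pseudo"] = lu
            components["n_confident"] = n_conf

        if config.use_consistency:
            components["consistency"] = consistency_loss(
                student.predict_from_features, outs.penultimate,
                config.loss.perturb_prob, perturb_rng)

        if config.use_reconstruction:
            recon, latent = student.forward_reconstruction(outs.encoder_out, eps_rng)
            components["reconstruction"] = reconstruction_loss(
                recon, batch.images, latent.mu, latent.log_var,
                config.loss.kl_weight)

        loss, report = total_loss(components, config.loss, it)
        if not np.isfinite(report.total):
            raise RuntimeError(
                f"non-finite loss at iteration {it}: "
                f"ls={report.ls} lu={report.lu} lc={report.lc} lrec={report.lrec}")
        optimizer.zero_grad()
        loss.backward()
        lr_t = cosine_lr(it, config.iterations, config.lr, config.lr_floor)
        optimizer.step(lr=lr_t)
        if ema is not None:
            ema_update(ema)

        row = {"iteration": it, "lr": lr_t, "ls": report.ls,
               "delta": report.delta, "total": report.total}
        if config.use_pseudo and use_unlabeled:
            row["lu"] = report.lu
            row["n_confident"] = report.n_confident
        if config.use_consistency:
            row["lc"] = report.lc
        if config.use_reconstruction:
            row["lrec"] = report.lrec
        rows.append(row)

    return TrainResult(student=student, teacher=teacher, log=pd.DataFrame(rows),
                       config=config, train_subjects=subjects,
                       split_hash=split_hash(subjects))


def predict_subject(model: UNet2D, subject: Subject) -> np.ndarray:
    """Whole-image argmax segmentation of one subject."""
    img = normalize_image(subject.volume)[None, None]
    return model.forward_inference(img)[0]


def evaluate(model: UNet2D, subjects: list[Subject],
             use_ground_truth: bool = True) -> pd.DataFrame:
    """Per-subject metric table plus an aggregate "mean" row.

    Subjects without any reference mask are skipped.  Undefined surface
    metrics propagate as NaN and are excluded from means.
    """
    rows = []
    for s in subjects:
        ref = s.ground_truth if use_ground_truth else s.mask
        if ref is None:
            continue
        pred = predict_subject(model, s)
        rep = evaluate_volume(pred, ref, spacing=None)
        rows.append({"subject_id": s.id, "dice": rep.dice, "iou": rep.iou,
                     "hd95": rep.hd95, "asd": rep.asd})
    df = pd.DataFrame(rows)
    if len(df):
        agg = {"subject_id": "mean"}
        for key in ("dice", "iou", "hd95", "asd"):
            agg[key] = float(np.nanmean(df[key].to_numpy(dtype=float)))
        df = pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
    return df


ABLATION_ARMS = {
    "full": {},
    "no_consistency": {"use_consistency": False},
    "no_pseudo": {"use_pseudo": False},
    "no_reconstruction": {"use_reconstruction": False},
    "no_teacher_student": {"use_teacher_student": False},
    "supervised_only": {"use_pseudo": False, "use_consistency": False,
                        "use_reconstruction": False,
                        "use_teacher_student": False},
}


def run_ablation(config: ExperimentConfig, arms=("full", "no_consistency",
                                                 "no_pseudo",
                                                 "no_reconstruction")) -> pd.DataFrame:
    """Train each arm on the identical split and score it on held-out data."""
    unknown = set(arms) - set(ABLATION_ARMS)
    if unknown:
        raise ValueError(f"unknown ablation arms: {sorted(unknown)}")
    train_subjects, test_subjects = _generate_corpus(config)
    rows = []
    for arm in arms:
        arm_cfg = replace(config, **ABLATION_ARMS[arm])
        result = train(arm_cfg, subjects=train_subjects)
        table = evaluate(result.student, test_subjects)
        mean = table[table.subject_id == "mean"].iloc[0]
        rows.append({"arm": arm, "dice": mean.dice, "iou": mean.iou,
                     "hd95": mean.hd95, "asd": mean.asd,
                     "split_hash": result.split_hash})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, result: TrainResult) -> None:
    """Store student (and teacher) weights plus the model hyperparameters."""
    cfg = result.config
    arrays = {f"student/{k}": v for k, v in result.student.state_dict().items()}
    if result.teacher is not None:
        arrays.update({f"teacher/{k}": v for k, v in result.teacher.state_dict().items()})
    meta = np.array([cfg.data.n_classes, cfg.base_channels, cfg.depth,
                     cfg.latent_dim,
                     *(cfg.patch_size or result.train_subjects[0].volume.shape)])
    np.savez(path, __meta__=meta, **arrays)


def load_checkpoint(path) -> tuple[UNet2D, UNet2D | None]:
    with np.load(path) as z:
        meta = z["__meta__"]
        n_classes, base, depth, latent = (int(x) for x in meta[:4])
        input_size = tuple(int(x) for x in meta[4:])
        student = UNet2D(1, n_classes, base_channels=base, depth=depth,
                         latent_dim=latent, input_size=input_size,
                         with_projector=True, rng=np.random.default_rng(0))
        student.load_state_dict({k[len("student/"):]: z[k] for k in z.files
                                 if k.startswith("student/")})
        teacher_keys = [k for k in z.files if k.startswith("teacher/")]
        teacher = None
        if teacher_keys:
            teacher = student.make_teacher()
            teacher.load_state_dict({k[len("teacher/"):]: z[k] for k in teacher_keys})
    return student, teacher
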