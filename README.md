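# semiseg

Semi-supervised training for MRI segmentation when only a small fraction
of subjects carries expert masks. A student UNet learns from the labeled
pool in the ordinary supervised way and from the unlabeled pool through
three auxiliary mechanisms around an exponential-moving-average (EMA)
teacher:

* **pseudo-labeling** — the teacher's argmax predictions on unlabeled
  pixels become cross-entropy targets, gated by a confidence threshold
  τ₁ (default 0.9):

      L_U = 1/(HWN₂) Σₙ Σᵢ 1[max Pₙᵢ ≥ τ₁] · H(Ŷₙᵢ, Pₙᵢ),  Ŷₙᵢ = argmax Pₙᵢ

* **consistency under feature perturbation** — predictions must agree
  before and after adding N(0,1) noise to 5% of the decoder features fed
  to the final prediction layer;
* **variational reconstruction** — a conditional-VAE head
  (z = μ + σ⊙ε from the encoder bottleneck) reconstructs the input
  image under an MSE loss.

The supervised loss is cross-entropy plus soft Dice; unsupervised terms
are weighted by the Gaussian ramp-up δ(t) = exp(−5(1 − min(t,T)/T)²).
The teacher follows φ ← ηφ + (1−η)θ with η = 0.95 and supplies the
pseudo-labels. Evaluation ships Dice, IoU, 95th-percentile Hausdorff
distance and average surface distance, all tested against brute-force
oracles. A synthetic-corpus generator stands in for cardiac MRI cohorts
(subject-level labeled/unlabeled splits, small foreground fraction,
per-subject contrast and noise variation, bias-field-like smooth noise).

Everything runs on CPU: the package includes a small reverse-mode
autodiff engine over NumPy with numba-compiled convolution kernels —
no GPU framework required.

## Worked example

```python
from dataclasses import replace
from semiseg import ExperimentConfig, SyntheticConfig, train, evaluate
from semiseg.losses import LossConfig
from semiseg.trainer import ABLATION_ARMS, _generate_corpus

cfg = ExperimentConfig(
    data=SyntheticConfig(n_subjects=100, labeled_proportion=0.1, seed=0),
    iterations=400, lr=2e-3,
    loss=LossConfig(rampup_len=100, w_reconstruction=0.05), seed=0)
train_subjects, test_subjects = _generate_corpus(cfg)

full = train(cfg, subjects=train_subjects)                  # three branches + teacher
sup = train(replace(cfg, **ABLATION_ARMS["supervised_only"]),
            subjects=train_subjects)                        # plain UNet baseline

for name, res in [("full", full), ("supervised", sup)]:
    t = evaluate(res.student, test_subjects)
    print(name, t[t.subject_id == "mean"].round(4).to_string(index=False))
```

Output from this exact script (one CPU, a few minutes):

```
full subject_id   dice    iou   hd95    asd
      mean 0.9112 0.8525 6.2886 1.1325
supervised subject_id   dice    iou   hd95    asd
      mean 0.9134 0.8583 5.0399 0.9826
```

`dice`/`iou` are overlap scores in [0, 1] (higher is better) averaged
over 20 held-out subjects; `hd95`/`asd` are boundary distances in voxel
units (lower is better). With 10 of 100 training subjects labeled, the
full model and the supervised baseline land within a quarter Dice point
of each other on this seed. At this desk scale the pseudo-labeling and
consistency branches carry the semi-supervised benefit (dropping the
reconstruction branch on harder corpora raises held-out Dice by several
points over the baseline), while the variational reconstruction branch
competes with segmentation for the tiny encoder's capacity — see
`docs/methods.md` for the analysis and for what the synthetic world
does and does not establish.

There is also a CLI for the same workflow:

```sh
semiseg generate --config cfg.yaml --out data/
semiseg train    --config cfg.yaml --ckpt model.npz --log log.csv
semiseg eval     --ckpt model.npz --data data/ --csv results.csv
semiseg ablate   --config cfg.yaml --arms full,no_pseudo,supervised_only
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main end-to-end result from scratch: it
generates a seeded synthetic corpus, trains the full three-branch
teacher-student model and the supervised-only baseline at an equal
iteration budget, evaluates both on held-out subjects, and prints the
comparison before writing the results file.
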