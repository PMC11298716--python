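"""Encoder-decoder segmentation networks.

A 2-D UNet produces, besides class logits, the two internal feature maps the
semi-supervised branches need:

* ``penultimate`` -- the decoder feature map I fed to the final prediction
  convolution h; the consistency branch perturbs this map.  On a *student*
  network a 1x1 projector convolution is applied to I before h.
* ``encoder_out`` -- the bottleneck features E(X) conditioning the
  variational reconstruction branch, which samples a latent
  z = mu + sigma * eps and decodes it (concatenated channel-wise with a
  spatially tiled z) back to image space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, no_grad
from .nn import Conv2d, ConvBlock, Linear, Module, softmax

__all__ = ["NetworkOutputs", "LatentState", "UNet2D", "reparameterize"]


@dataclass
class NetworkOutputs:
    """Everything a single segmentation forward pass produces."""

    logits: Tensor          # (B, C, H, W) pre-softmax scores
    probs: Tensor           # softmax of logits over the class axis
    penultimate: Tensor     # feature map I fed to the prediction layer h
    encoder_out: Tensor     # bottleneck features E(X)


@dataclass
class LatentState:
    """Latent draw of the reconstruction branch: z = mu + exp(log_var/2)*eps."""

    mu: Tensor
    log_var: Tensor
    z: Tensor
    epsilon: np.ndarray = field(repr=False, default=None)


def reparameterize(mu: Tensor, log_var: Tensor,
                   rng: np.random.Generator) -> LatentState:
    """Sample z = mu + sigma * eps with eps ~ N(0, I).

    The noise draw is a constant, so gradients flow to ``mu`` and
    ``log_var`` only.
    """
    eps = rng.standard_normal(mu.shape).astype(mu.data.dtype, copy=False)
    sigma = (log_var * 0.5).exp()
    z = mu + sigma * eps
    return LatentState(mu=mu, log_var=log_var, z=z, epsilon=eps)


class UNet2D(Module):
    """Small configurable UNet with projector and cVAE reconstruction head.

    Parameters
    ----------
    in_channels, n_classes : int
        Image channels and segmentation classes.
    base_channels : int
        Channels of the first stage; doubled at every downsampling.
    depth : int
        Number of 2x downsamplings (1 gives the desk-scale 2-level UNet,
        4 the full-scale variant).
    latent_dim : int
        Dimension of the variational latent z.
    input_size : (int, int)
        Training image size; fixes the flattened bottleneck size the two
        fully connected latent heads operate on.
    with_projector : bool
        Student networks carry the extra 1x1 projector; teachers do not.
    """

    def __init__(self, in_channels: int = 1, n_classes: int = 2,
                 base_channels: int = 8, depth: int = 1, latent_dim: int = 16,
                 input_size: tuple[int, int] = (64, 64),
                 with_projector: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if any(s % (2 ** depth) for s in input_size):
            raise ValueError(f"input size {input_size} not divisible by 2^{depth}")
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.depth = depth
        self.latent_dim = latent_dim
        self.input_size = tuple(input_size)

        ch = [base_channels * 2 ** l for l in range(depth + 1)]
        self.enc_blocks = [ConvBlock(in_channels if l == 0 else ch[l], ch[l], rng=rng)
                           for l in range(depth)]
        self.down_convs = [Conv2d(ch[l], ch[l + 1], 3, stride=2, rng=rng)
                           for l in range(depth)]
        self.bottleneck = ConvBlock(ch[depth], ch[depth], rng=rng)
        self.up_convs = [Conv2d(ch[l + 1], ch[l], 3, rng=rng) for l in range(depth)]
        self.dec_blocks = [ConvBlock(2 * ch[l], ch[l], rng=rng) for l in range(depth)]
        self.head = Conv2d(ch[0], n_classes, 1, rng=rng)

        self.projector = Conv2d(ch[0], ch[0], 1, rng=rng) if with_projector else None
        if self.projector is not None:
            # identity start: a fresh student matches its teacher exactly
            self.projector.set_identity()

        hb, wb = input_size[0] // 2 ** depth, input_size[1] // 2 ** depth
        self._bottleneck_hw = (hb, wb)
        flat = ch[depth] * hb * wb
        self.mu_head = Linear(flat, latent_dim, rng=rng)
        self.logvar_head = Linear(flat, latent_dim, rng=rng)
        # reconstruction decoder mirrors the upsampling ladder, own weights
        self.rec_in = Conv2d(ch[depth] + latent_dim, ch[depth], 3, rng=rng)
        self.rec_ups = [Conv2d(ch[l + 1], ch[l], 3, rng=rng) for l in reversed(range(depth))]
        self.rec_out = Conv2d(ch[0], in_channels, 1, rng=rng)

    # -- segmentation path ---------------------------------------------------
    def forward(self, x: Tensor) -> NetworkOutputs:
        x = Tensor(x) if isinstance(x, np.ndarray) else x
        dtype = self.head.weight.data.dtype
        if x.data.dtype != dtype and not x.requires_grad:
            x = Tensor(x.data.astype(dtype))
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (B, {self.in_channels}, H, W), got {x.shape}")
        if any(s % (2 ** self.depth) for s in x.shape[2:]):
            raise ValueError(
                f"spatial dims {x.shape[2:]} not divisible by 2^{self.depth}")
        skips = []
        h = x
        for enc, down in zip(self.enc_blocks, self.down_convs):
            h = enc(h)
            skips.append(h)
            h = down(h).relu()
        encoder_out = self.bottleneck(h)
        h = encoder_out
        for l in reversed(range(self.depth)):
            h = self.up_convs[l](h.upsample2_nearest()).relu()
            h = self.dec_blocks[l](concat([skips[l], h], axis=1))
        penult = self.projector(h) if self.projector is not None else h
        logits = self.head(penult)
        return NetworkOutputs(logits=logits, probs=softmax(logits),
                              penultimate=penult, encoder_out=encoder_out)

    def predict_from_features(self, features: Tensor) -> Tensor:
        """Apply the prediction layer h to a (possibly perturbed) feature map."""
        return self.head(features)

    # -- reconstruction path -------------------------------------------------
    def latent_params(self, encoder_out: Tensor) -> tuple[Tensor, Tensor]:
        """Two independent affine heads mapping flattened E(X) to mu, log sigma^2."""
        b = encoder_out.shape[0]
        flat = encoder_out.reshape(b, -1)
        return self.mu_head(flat), self.logvar_head(flat)

    def reconstruct(self, z: Tensor, encoder_out: Tensor) -> Tensor:
        """Decode (z, E(X)) back to image space.

        z is tiled over the bottleneck grid and concatenated channel-wise
        with E(X) before the (independent) upsampling decoder.
        """
        b, _, hb, wb = encoder_out.shape
        if z.shape[0] != b:
            raise ValueError("batch mismatch between z and encoder output")
        z_map = z.reshape(b, self.latent_dim, 1, 1) * np.ones(
            (1, 1, hb, wb), dtype=encoder_out.data.dtype)
        h = self.rec_in(concat([encoder_out, z_map], axis=1)).relu()
        for up in self.rec_ups:
            h = up(h.upsample2_nearest()).relu()
        return self.rec_out(h)

    def forward_reconstruction(self, encoder_out: Tensor,
                               rng: np.random.Generator) -> tuple[Tensor, LatentState]:
        mu, log_var = self.latent_params(encoder_out)
        latent = reparameterize(mu, log_var, rng)
        return self.reconstruct(latent.z, encoder_out), latent

    # -- teacher construction ------------------------------------------------
    def projector_param_names(self) -> set[str]:
        if self.projector is None:
            return set()
        return {n for n, _ in self.named_parameters() if n.startswith("projector.")}

    def make_teacher(self) -> "UNet2D":
        """A projector-free deep copy sharing this network's current weights."""
        teacher = UNet2D(self.in_channels, self.n_classes,
                         base_channels=self.enc_blocks[0].conv1.weight.shape[0],
                         depth=self.depth, latent_dim=self.latent_dim,
                         input_size=self.input_size, with_projector=False,
                         rng=np.random.default_rng(0))
        proj = self.projector_param_names()
        state = {k: v for k, v in self.state_dict().items() if k not in proj}
        teacher.load_state_dict(state)
        for p in teacher.parameters():
            p.requires_grad = False
        return teacher

    def forward_inference(self, x) -> np.ndarray:
        """Argmax label map without building a tape (B, H, W)."""
        with no_grad():
            out = self.forward(x)
        return np.argmax(out.logits.data, axis=1)
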