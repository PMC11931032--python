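"""Sketch-to-photo conditional GAN with an SSIM-weighted objective.

The generator encodes a single-channel sketch through stride-2 4x4
convolutions (64/128/256/512 by default), passes nine 3x3 residual
blocks, decodes with transposed convolutions and emits a 3-channel Tanh
output.  The discriminator is a pix2pix-style patch network that sees
the sketch concatenated with the (real or generated) photo; its patch
score map is averaged to one scalar logit per pair.

The generator minimizes ``lambda_adv * L_adv + lambda_ssi * (1 - SSIM)``
with the non-saturating binary cross-entropy adversarial term and the
weights fixed at 0.8 / 0.2.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .deblur import ResidualBlock, TrainConfig, _check_finite
from .dssim import ssim_graph
from .exceptions import CatDeblurError, ShapeError


@dataclass(frozen=True)
class TranslatorSpec:
    gen_down_filters: tuple = (64, 128, 256, 512)
    n_residual_blocks: int = 9
    gen_up_filters: tuple = (512, 256, 128, 64)
    down_kernel: int = 4
    residual_kernel: int = 3
    output_kernel: int = 4
    disc_filters: tuple = (64, 128, 256, 512)
    disc_kernel: int = 4
    leaky_slope: float = 0.2
    bn_momentum: float = 0.999
    patch_based: bool = True

    def __post_init__(self):
        if len(self.gen_down_filters) != len(self.gen_up_filters):
            raise CatDeblurError("need as many up stages as down stages")
        if min((*self.gen_down_filters, *self.gen_up_filters, *self.disc_filters)) <= 0:
            raise CatDeblurError("filter counts must be positive")


@dataclass(frozen=True)
class LossWeights:
    lambda_adv: float = 0.8
    lambda_ssi: float = 0.2

    def __post_init__(self):
        if self.lambda_adv < 0 or self.lambda_ssi < 0:
            raise CatDeblurError("loss weights must be non-negative")


class TranslatorGenerator(nn.Module):
    def __init__(self, spec: TranslatorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        k = spec.down_kernel
        downs, c = [], 1
        kpad = (k - 2) // 2 if k % 2 == 0 else k // 2   # exact halving at stride 2
        for i, f in enumerate(spec.gen_down_filters):
            downs.append(nn.Conv2d(c, f, k, 2, kpad, rng=rng))
            downs.append(nn.InstanceNorm2d(f) if i > 0 else nn.Identity())
            c = f
        self.downs = downs
        self.res_blocks = [ResidualBlock(c, spec.residual_kernel, rng)
                           for _ in range(spec.n_residual_blocks)]
        ups = []
        for f in spec.gen_up_filters:
            ups.append(nn.ConvTranspose2d(c, f, k, 2, (k - 2) // 2 if k % 2 == 0 else 1,
                                          output_padding=0 if k % 2 == 0 else 1, rng=rng))
            ups.append(nn.InstanceNorm2d(f))
            c = f
        self.ups = ups
        ko = spec.output_kernel
        # even output kernels need asymmetric same-padding: total pad = ko - 1
        pad = ((ko // 2 - 1, ko // 2), (ko // 2 - 1, ko // 2)) if ko % 2 == 0 else ko // 2
        self.out_conv = nn.Conv2d(c, 3, ko, 1, pad, rng=rng, w_scale=0.2)

    @property
    def n_residual_blocks(self) -> int:
        return len(self.res_blocks)

    @property
    def downsample_factor(self) -> int:
        return 2 ** len(self.spec.gen_down_filters)

    def forward(self, x):
        f = self.downsample_factor
        H, W = x.shape[-2:]
        if H % f or W % f:
            raise ShapeError(f"input sides must be divisible by {f}, got {H}x{W}")
        h = x
        for i in range(0, len(self.downs), 2):
            h = ad.relu(self.downs[i + 1](self.downs[i](h)))
        for block in self.res_blocks:
            h = block(h)
        for i in range(0, len(self.ups), 2):
            h = ad.relu(self.ups[i + 1](self.ups[i](h)))
        return ad.tanh(self.out_conv(h))


class PatchDiscriminator(nn.Module):
    """Conditional patch discriminator over (sketch, photo) channel stacks."""

    def __init__(self, spec: TranslatorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        k = spec.disc_kernel
        layers, c = [], 4
        for i, f in enumerate(spec.disc_filters):
            stride = 2 if i < len(spec.disc_filters) - 1 else 1
            layers.append(nn.Conv2d(c, f, k, stride, 1, rng=rng))
            if i > 0:
                layers.append(nn.BatchNorm2d(f, momentum=spec.bn_momentum))
            layers.append(nn.LeakyReLU(spec.leaky_slope))
            c = f
        self.features = nn.Sequential(layers)
        self.patch_head = nn.Conv2d(c, 1, k, 1, 1, rng=rng)
        self.leaky_slope = spec.leaky_slope

    def patch_map(self, sketch, photo):
        if sketch.shape[-2:] != photo.shape[-2:]:
            raise ShapeError("sketch and photo sizes differ")
        x = ad.concat([sketch, photo], axis=1)
        out = self.patch_head(self.features(x))
        if 0 in out.shape:
            raise ShapeError(f"input {tuple(sketch.shape[-2:])} too small for the "
                             f"patch discriminator (empty score map)")
        return out

    def forward(self, sketch, photo):
        """Scalar logit per pair: the mean of the patch score map."""
        return ad.tmean(self.patch_map(sketch, photo), axis=(1, 2, 3))

    def __call__(self, sketch, photo):
        return self.forward(sketch, photo)


def build_translator_generator(spec: TranslatorSpec | None = None, seed: int = 0,
                               rng: np.random.Generator | None = None) -> TranslatorGenerator:
    return TranslatorGenerator(spec or TranslatorSpec(), rng or np.random.default_rng(seed))


def build_patch_discriminator(spec: TranslatorSpec | None = None, seed: int = 0,
                              rng: np.random.Generator | None = None) -> PatchDiscriminator:
    return PatchDiscriminator(spec or TranslatorSpec(), rng or np.random.default_rng(seed))


def ssi_loss(generated, target) -> float:
    """Structural-similarity loss ``1 - mean SSIM`` on [-1, 1] batches.

    Accepts (B, C, H, W) arrays; bounded in [0, 2] since SSIM is in
    [-1, 1].
    """
    g = np.asarray(generated, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if g.shape != t.shape:
        raise ShapeError(f"batch shapes differ: {g.shape} vs {t.shape}")
    from .metrics import ssim as ssim_metric

    vals = []
    for gi, ti in zip(g, t):
        a = np.clip((np.moveaxis(gi, 0, -1) + 1) * 127.5, 0, 255)
        b = np.clip((np.moveaxis(ti, 0, -1) + 1) * 127.5, 0, 255)
        if a.shape[-1] == 1:
            a, b = a[..., 0], b[..., 0]
        vals.append(ssim_metric(a, b))
    return float(1.0 - np.mean(vals))


def total_loss(adv_term: float, ssi_term: float, w: LossWeights | None = None) -> float:
    w = w or LossWeights()
    return w.lambda_adv * adv_term + w.lambda_ssi * ssi_term


def _bce_real(logit: Tensor) -> Tensor:
    """Binary cross-entropy against label 1, from logits: softplus(-x)."""
    return ad.tmean(ad.softplus(-logit))


def _bce_fake(logit: Tensor) -> Tensor:
    """Binary cross-entropy against label 0, from logits: softplus(x)."""
    return ad.tmean(ad.softplus(logit))


def train_translator(pairs, spec: TranslatorSpec | None = None,
                     weights: LossWeights | None = None,
                     cfg: TrainConfig | None = None, checkpoint_dir=None):
    """Alternating cGAN training on (sketch [0,255] HxW, photo [0,255] HxWx3) pairs."""
    spec = spec or TranslatorSpec()
    weights = weights or LossWeights()
    cfg = cfg or TrainConfig()
    if not pairs:
        raise CatDeblurError("training corpus is empty")
    S = np.stack([np.asarray(p[0], dtype=np.float32) for p in pairs])[:, None] / 127.5 - 1.0
    P = np.stack([np.moveaxis(np.asarray(p[1], dtype=np.float32), -1, 0)
                  for p in pairs]) / 127.5 - 1.0
    N = S.shape[0]

    rng = np.random.default_rng(cfg.seed)
    gen = TranslatorGenerator(spec, rng)
    disc = PatchDiscriminator(spec, rng)
    opt_g = nn.Adam(gen.parameters(), cfg.lr_generator, cfg.beta1, cfg.beta2)
    opt_d = nn.Adam(disc.parameters(), cfg.lr_discriminator, cfg.beta1, cfg.beta2)

    ema = [np.array(p.data, copy=True) for p in gen.parameters()]
    # best-checkpoint selection: adversarial training can destabilize late,
    # so the returned generator is the EMA snapshot taken where the smoothed
    # *training* SSI term was lowest (no held-out data involved)
    ssi_smooth, best_ssi, best_snapshot = None, np.inf, None

    steps_per_epoch = max(1, N // cfg.batch_size)
    history, gen_step = [], 0
    for epoch in range(cfg.epochs):
        for _ in range(steps_per_epoch):
            if cfg.lr_decay_step and gen_step == cfg.lr_decay_step:
                opt_g.lr *= cfg.lr_decay_factor
                opt_d.lr *= cfg.lr_decay_factor
            idx = rng.integers(0, N, cfg.batch_size)
            s, p = Tensor(S[idx]), Tensor(P[idx])
            with ad.no_grad():
                fake = gen(s).data
            d_loss = ad.add(_bce_real(disc(s, p)), _bce_fake(disc(s, Tensor(fake))))
            opt_d.zero_grad()
            ad.backward(d_loss, opt_d.params)
            opt_d.step()

            idx = rng.integers(0, N, cfg.batch_size)
            s, p = Tensor(S[idx]), Tensor(P[idx])
            fake = gen(s)
            adv = _bce_real(disc(s, fake))
            ssi = ad.add(1.0, -ssim_graph(fake, p))
            g_loss = ad.add(ad.mul(adv, weights.lambda_adv), ad.mul(ssi, weights.lambda_ssi))
            opt_g.zero_grad()
            ad.backward(g_loss, opt_g.params)
            opt_g.step()
            gen_step += 1
            for buf, p in zip(ema, gen.parameters()):
                buf *= cfg.ema_decay
                buf += (1 - cfg.ema_decay) * p.data
            ssi_val = ssi.item()
            ssi_smooth = ssi_val if ssi_smooth is None else 0.96 * ssi_smooth + 0.04 * ssi_val
            if gen_step >= 50 and ssi_smooth < best_ssi:
                best_ssi = ssi_smooth
                best_snapshot = [np.array(b, copy=True) for b in ema]

            _check_finite(d_loss.item(), g_loss.item())
            history.append({"step": gen_step, "epoch": epoch, "disc_loss": d_loss.item(),
                            "adv": adv.item(), "ssi": ssi.item(), "total": g_loss.item()})
            if checkpoint_dir and cfg.checkpoint_every and gen_step % cfg.checkpoint_every == 0:
                nn.save_checkpoint(gen, f"{checkpoint_dir}/translator_gen_{gen_step:06d}.npz",
                                   meta={"spec": spec.__dict__, "cfg": cfg.__dict__,
                                         "weights": weights.__dict__, "step": gen_step})
    final = best_snapshot if best_snapshot is not None else ema
    for buf, p in zip(final, gen.parameters()):
        p.data = buf.astype(p.dtype)
    if checkpoint_dir:
        nn.save_checkpoint(gen, f"{checkpoint_dir}/translator_gen_final.npz",
                           meta={"spec": spec.__dict__, "cfg": cfg.__dict__,
                                 "weights": weights.__dict__, "step": gen_step})
    return gen, history


def translate(generator: TranslatorGenerator, sketch: np.ndarray) -> np.ndarray:
    """Run the generator on a [0,255] grayscale sketch -> HxWx3 photo in [0,255]."""
    sketch = np.asarray(sketch, dtype=np.float64)
    if sketch.ndim != 2:
        raise ShapeError(f"expected a 2-D sketch, got shape {sketch.shape}")
    generator.eval()
    with ad.no_grad():
        x = (sketch[None, None].astype(np.float32)) / 127.5 - 1.0
        out = generator(Tensor(x)).data
    generator.train()
    photo = np.clip((np.asarray(out[0], dtype=np.float64) + 1.0) * 127.5, 0, 255)
    return np.moveaxis(photo, 0, -1)
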