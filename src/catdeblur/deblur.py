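"""Sketch-deblurring GAN: residual generator + Wasserstein critic with
gradient penalty.

The generator is a DeblurGAN-style residual encoder-decoder: an initial
64-filter 3x3 convolution, two stride-2 downsampling convolutions (128,
256 filters), nine residual blocks, two transposed-convolution
upsampling stages (128, 64) and a 7x7 output convolution with Tanh, so
pixels live in [-1, 1].  A global skip connection (standard in the
DeblurGAN lineage) makes the freshly initialized generator approximate
the identity, which keeps early training stable.

The critic scores images with four 4x4 convolutions (64/128/256/512,
stride 2 except the last), LeakyReLU(0.2), batch normalization
(momentum 0.999) on all layers but the first, and a single-neuron dense
head.  Training follows the WGAN-GP recipe: the critic maximizes
``E D(real) - E D(fake)`` subject to a gradient penalty
``lambda * E (||grad D(xhat)||_2 - 1)^2`` on random interpolates, and
the generator minimizes ``-E D(fake)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .exceptions import CatDeblurError, ShapeError, TrainingDivergenceError


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description for the deblurring generator and critic."""

    initial_filters: int = 64
    down_filters: tuple = (128, 256)
    n_residual_blocks: int = 9
    up_filters: tuple = (128, 64)
    initial_kernel: int = 3
    down_kernel: int = 3
    residual_kernel: int = 3
    output_kernel: int = 7
    activation_out: str = "tanh"
    disc_filters: tuple = (64, 128, 256, 512)
    disc_kernel: int = 4
    leaky_slope: float = 0.2
    bn_momentum: float = 0.999
    critic_norm: str = "batch"          # batch | instance | none
    global_skip: bool = True

    def __post_init__(self):
        if min((self.initial_filters, *self.down_filters, *self.up_filters,
                *self.disc_filters)) <= 0:
            raise CatDeblurError("filter counts must be positive")
        if not 0 < self.leaky_slope < 1:
            raise CatDeblurError("leaky_slope must lie in (0,1)")
        if not 0 < self.bn_momentum < 1:
            raise CatDeblurError("bn_momentum must lie in (0,1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters; the Adam betas follow the WGAN setup."""

    lr_generator: float = 2e-4
    lr_discriminator: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    gp_weight: float = 10.0
    critic_steps_per_gen: int = 5
    batch_size: int = 4
    epochs: int = 10
    seed: int = 0
    checkpoint_every: int = 0           # generator steps; 0 disables
    early_stop_tol: float = 0.0         # |E D(real) - E D(fake)| tolerance; 0 disables
    early_stop_patience: int = 5
    ema_decay: float = 0.98             # weight averaging for the returned generator
    lr_decay_step: int = 0              # generator step at which to decay lrs; 0 disables
    lr_decay_factor: float = 0.3

    def __post_init__(self):
        if min(self.lr_generator, self.lr_discriminator) <= 0:
            raise CatDeblurError("learning rates must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise CatDeblurError("Adam betas must lie in (0,1)")


class ResidualBlock(nn.Module):
    """conv -> instance norm -> ReLU -> conv -> instance norm, plus skip."""

    def __init__(self, c, k=3, rng=None):
        super().__init__()
        p = k // 2
        self.conv1 = nn.Conv2d(c, c, k, 1, p, rng=rng)
        self.norm1 = nn.InstanceNorm2d(c)
        self.conv2 = nn.Conv2d(c, c, k, 1, p, rng=rng)
        self.norm2 = nn.InstanceNorm2d(c)

    def forward(self, x):
        h = ad.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return ad.add(x, h)


class DeblurGenerator(nn.Module):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        k, kd = spec.initial_kernel, spec.down_kernel
        self.initial = nn.Conv2d(1, spec.initial_filters, k, 1, k // 2, rng=rng)
        self.initial_norm = nn.InstanceNorm2d(spec.initial_filters)
        downs, c = [], spec.initial_filters
        for f in spec.down_filters:
            downs.append(nn.Conv2d(c, f, kd, 2, kd // 2, rng=rng))
            downs.append(nn.InstanceNorm2d(f))
            c = f
        self.downs = downs
        self.res_blocks = [ResidualBlock(c, spec.residual_kernel, rng)
                           for _ in range(spec.n_residual_blocks)]
        ups = []
        for f in spec.up_filters:
            ups.append(nn.ConvTranspose2d(c, f, 3, 2, 1, output_padding=1, rng=rng))
            ups.append(nn.InstanceNorm2d(f))
            c = f
        self.ups = ups
        ko = spec.output_kernel
        # small-scale output weights keep the global skip near-identity at init
        self.out_conv = nn.Conv2d(c, 1, ko, 1, ko // 2, rng=rng, w_scale=0.01)

    @property
    def n_residual_blocks(self) -> int:
        return len(self.res_blocks)

    @property
    def downsample_factor(self) -> int:
        return 2 ** len(self.spec.down_filters)

    def forward(self, x):
        self._check_size(x)
        h = ad.relu(self.initial_norm(self.initial(x)))
        for i in range(0, len(self.downs), 2):
            h = ad.relu(self.downs[i + 1](self.downs[i](h)))
        for block in self.res_blocks:
            h = block(h)
        for i in range(0, len(self.ups), 2):
            h = ad.relu(self.ups[i + 1](self.ups[i](h)))
        pre = self.out_conv(h)
        if self.spec.global_skip:
            skip = np.arctanh(np.clip(x.data, -0.999, 0.999))
            pre = ad.add(pre, Tensor(skip.astype(pre.dtype)))
        return ad.tanh(pre)

    def _check_size(self, x):
        f = self.downsample_factor
        H, W = x.shape[-2:]
        if H % f or W % f:
            raise ShapeError(f"input sides must be divisible by {f}, got {H}x{W}")


class DeblurCritic(nn.Module):
    """Convolutional critic emitting one unbounded scalar score per image."""

    def __init__(self, spec: NetworkSpec, input_size: int = 64,
                 rng: np.random.Generator | None = None, in_channels: int = 1):
        super().__init__()
        self.spec = spec
        k = spec.disc_kernel
        layers, c, s = [], in_channels, input_size
        for i, f in enumerate(spec.disc_filters):
            stride = 2 if i < len(spec.disc_filters) - 1 else 1
            layers.append(nn.Conv2d(c, f, k, stride, 1, rng=rng))
            if i > 0:
                layers.append(nn.make_norm(spec.critic_norm, f, spec.bn_momentum))
            layers.append(nn.LeakyReLU(spec.leaky_slope))
            s = (s + 2 - k) // stride + 1
            c = f
        self.features = nn.Sequential(layers)
        self.head = nn.Dense(c * s * s, 1, rng=rng)
        self.leaky_slope = spec.leaky_slope

    def forward(self, x):
        return self.head(self.features(x))


def build_deblur_generator(spec: NetworkSpec | None = None, seed: int = 0,
                           rng: np.random.Generator | None = None) -> DeblurGenerator:
    return DeblurGenerator(spec or NetworkSpec(), rng or np.random.default_rng(seed))


def build_deblur_critic(spec: NetworkSpec | None = None, input_size: int = 64,
                        seed: int = 0, rng: np.random.Generator | None = None) -> DeblurCritic:
    return DeblurCritic(spec or NetworkSpec(), input_size, rng or np.random.default_rng(seed))


def wasserstein_distance_1d(p_samples, q_samples) -> float:
    """Exact W1 between two empirical 1-D distributions.

    Computed by sorted-quantile matching; serves as the transparent
    reference for what the critic approximates on image distributions.
    """
    p = np.asarray(list(p_samples), dtype=np.float64)
    q = np.asarray(list(q_samples), dtype=np.float64)
    if p.size == 0 or q.size == 0:
        raise CatDeblurError("sample lists must be non-empty")
    return float(stats.wasserstein_distance(p, q))


def _scores(critic, batch: Tensor) -> Tensor:
    s = critic(batch)
    if s.ndim > 1:
        s = ad.reshape(s, (s.shape[0],))
    return s


def critic_loss(critic, real_batch, fake_batch, gp_weight: float = 10.0,
                rng: np.random.Generator | None = None):
    """WGAN-GP critic objective with per-term breakdown.

    ``-E D(real) + E D(fake) + gp_weight * E (||grad D(xhat)|| - 1)^2``
    with ``xhat`` drawn uniformly on segments between paired real/fake
    samples.  Returns ``(loss, parts)`` where ``parts`` holds the three
    scalar terms.
    """
    rng = rng or np.random.default_rng(0)
    real = real_batch if isinstance(real_batch, Tensor) else Tensor(np.asarray(real_batch))
    fake = fake_batch if isinstance(fake_batch, Tensor) else Tensor(np.asarray(fake_batch))
    if real.shape != fake.shape:
        raise ShapeError(f"real {real.shape} and fake {fake.shape} batches differ in shape")

    real_term = ad.tmean(_scores(critic, real))
    fake_term = ad.tmean(_scores(critic, fake))

    eps_shape = (real.shape[0],) + (1,) * (real.ndim - 1)
    eps = rng.uniform(size=eps_shape).astype(real.dtype)
    xhat = Tensor(eps * real.data + (1 - eps) * fake.data, requires_grad=True)
    s = ad.tsum(_scores(critic, xhat))
    (g,) = ad.grad(s, [xhat], create_graph=True)
    axes = tuple(range(1, real.ndim))
    gnorm = ad.sqrt(ad.add(ad.tsum(ad.mul(g, g), axis=axes), 1e-12))
    gp = ad.tmean(ad.mul(ad.add(gnorm, -1.0), ad.add(gnorm, -1.0)))

    loss = ad.add(ad.add(-real_term, fake_term), ad.mul(gp, gp_weight))
    parts = {"real_term": -real_term.item(), "fake_term": fake_term.item(),
             "gradient_penalty": gp.item()}
    return loss, parts


def generator_loss_wasserstein(critic, fake_batch):
    """Generator objective ``-E D(fake)``."""
    fake = fake_batch if isinstance(fake_batch, Tensor) else Tensor(np.asarray(fake_batch))
    return -ad.tmean(_scores(critic, fake))


def _to_unit(images: np.ndarray) -> np.ndarray:
    """[0,255] gray stack -> float32 B x 1 x H x W in [-1,1]."""
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[:, None]
    return arr / 127.5 - 1.0


def _from_unit(batch: np.ndarray) -> np.ndarray:
    return np.clip((np.asarray(batch, dtype=np.float64) + 1.0) * 127.5, 0.0, 255.0)


def _check_finite(*values):
    for v in values:
        if not np.isfinite(v):
            raise TrainingDivergenceError(f"non-finite loss encountered: {values}")


def train_deblur(pairs, net_spec: NetworkSpec | None = None,
                 cfg: TrainConfig | None = None, checkpoint_dir=None):
    """Alternating WGAN-GP optimization on (input sketch, target sketch) pairs.

    ``pairs`` is a sequence of 2-tuples of [0,255] grayscale arrays.
    Returns ``(generator, history)``; ``history`` has one record per
    generator step.
    """
    spec = net_spec or NetworkSpec()
    cfg = cfg or TrainConfig()
    if not pairs:
        raise CatDeblurError("training corpus is empty")
    X = _to_unit(np.stack([np.asarray(p[0]) for p in pairs]))
    T = _to_unit(np.stack([np.asarray(p[1]) for p in pairs]))
    N, _, H, W = X.shape

    rng = np.random.default_rng(cfg.seed)
    gen = DeblurGenerator(spec, rng)
    critic = DeblurCritic(spec, input_size=H, rng=rng)
    opt_g = nn.Adam(gen.parameters(), cfg.lr_generator, cfg.beta1, cfg.beta2)
    opt_d = nn.Adam(critic.parameters(), cfg.lr_discriminator, cfg.beta1, cfg.beta2)

    # exponential moving average of generator weights; the averaged
    # network is what inference uses (standard GAN stabilization)
    ema = [np.array(p.data, copy=True) for p in gen.parameters()]

    steps_per_epoch = max(1, N // cfg.batch_size)
    history, gen_step, calm = [], 0, 0
    for epoch in range(cfg.epochs):
        for _ in range(steps_per_epoch):
            d_loss = d_parts = None
            for _ in range(cfg.critic_steps_per_gen):
                ir = rng.integers(0, N, cfg.batch_size)
                jf = rng.integers(0, N, cfg.batch_size)
                with ad.no_grad():
                    fake = gen(Tensor(X[jf])).data
                d_loss, d_parts = critic_loss(critic, T[ir], fake, cfg.gp_weight, rng)
                opt_d.zero_grad()
                ad.backward(d_loss, opt_d.params)
                opt_d.step()

            jg = rng.integers(0, N, cfg.batch_size)
            fake = gen(Tensor(X[jg]))
            g_loss = generator_loss_wasserstein(critic, fake)
            opt_g.zero_grad()
            ad.backward(g_loss, opt_g.params)
            opt_g.step()
            gen_step += 1
            for buf, p in zip(ema, gen.parameters()):
                buf *= cfg.ema_decay
                buf += (1 - cfg.ema_decay) * p.data

            _check_finite(d_loss.item(), g_loss.item())
            history.append({"step": gen_step, "epoch": epoch,
                            "critic_loss": d_loss.item(), "gen_loss": g_loss.item(),
                            **d_parts})
            if checkpoint_dir and cfg.checkpoint_every and gen_step % cfg.checkpoint_every == 0:
                nn.save_checkpoint(gen, f"{checkpoint_dir}/deblur_gen_{gen_step:06d}.npz",
                                   meta={"spec": spec.__dict__, "cfg": cfg.__dict__,
                                         "step": gen_step})
            if cfg.early_stop_tol > 0:
                gap = abs(d_parts["real_term"] + d_parts["fake_term"])
                calm = calm + 1 if gap < cfg.early_stop_tol else 0
        if cfg.early_stop_tol > 0 and calm >= cfg.early_stop_patience:
            break
    for buf, p in zip(ema, gen.parameters()):
        p.data = buf.astype(p.dtype)
    if checkpoint_dir:
        nn.save_checkpoint(gen, f"{checkpoint_dir}/deblur_gen_final.npz",
                           meta={"spec": spec.__dict__, "cfg": cfg.__dict__,
                                 "step": gen_step})
    return gen, history


def apply_deblur(generator: DeblurGenerator, sketch: np.ndarray) -> np.ndarray:
    """Run the generator on a [0,255] grayscale sketch, returning the same range."""
    sketch = np.asarray(sketch, dtype=np.float64)
    if sketch.ndim != 2:
        raise ShapeError(f"expected a 2-D sketch, got shape {sketch.shape}")
    generator.eval()
    with ad.no_grad():
        out = generator(Tensor(_to_unit(sketch[None]))).data
    generator.train()
    return _from_unit(out)[0, 0]
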