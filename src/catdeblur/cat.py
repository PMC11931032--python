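"""Contour Accentuation Technique (CAT).

A deterministic classical preprocessor that turns a color face photo
into a contour-accentuated grayscale sketch in three steps:

1. luminance grayscale conversion (ITU-R BT.601 weights),
2. Gaussian blending — a normalized Gaussian convolution that smooths
   light/dark transitions while keeping facial structure,
3. gamma contrast correction ``V_out = (V_in/255)^(1/gamma) * 255`` with
   the gamma chosen by the image's mean luminance (dark images get
   gamma > 1, light images gamma < 1).

All arithmetic is floating point; quantization to 8-bit happens only at
file output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ChannelCountError, KernelSpecError, ParameterError, SizeError

#: BT.601 luminance weights for R, G, B.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class GaussianKernelSpec:
    """Discrete Gaussian kernel: odd side length ``size``, std-dev ``sigma`` in px."""

    size: int = 7
    sigma: float = 2.0

    def __post_init__(self):
        if not isinstance(self.size, (int, np.integer)) or self.size < 3 or self.size % 2 == 0:
            raise KernelSpecError(f"kernel size must be an odd integer >= 3, got {self.size}")
        if self.sigma <= 0:
            raise KernelSpecError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class GammaPolicy:
    """Luminance-driven gamma selection.

    Images with mean gray level below ``luminance_threshold`` are "dark"
    and corrected with ``gamma_dark`` (> 1, brightening under the
    1/gamma exponent); otherwise ``gamma_light`` (< 1) is applied.  A
    mean exactly at the threshold counts as light.
    """

    gamma_dark: float = 1.5
    gamma_light: float = 0.7
    luminance_threshold: float = 127.5

    def __post_init__(self):
        if self.gamma_dark <= 1:
            raise ParameterError("gamma_dark must be > 1")
        if not 0 < self.gamma_light < 1:
            raise ParameterError("gamma_light must lie in (0, 1)")
        if not 0 <= self.luminance_threshold <= 255:
            raise ParameterError("luminance_threshold must lie in [0, 255]")


@dataclass(frozen=True)
class CatParams:
    kernel: GaussianKernelSpec = field(default_factory=GaussianKernelSpec)
    gamma_policy: GammaPolicy = field(default_factory=GammaPolicy)
    #: optional invert-and-divide (color-dodge) combination of the
    #: grayscale with its blend, producing a line-drawing look; off by
    #: default because the three canonical steps do not include it.
    dodge_blend: bool = False


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luminance: 0.299 R + 0.587 G + 0.114 B, floating point."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ChannelCountError(f"expected an HxWx3 image, got shape {img.shape}")
    w = np.asarray(GRAY_WEIGHTS, dtype=np.float64)
    return img.astype(np.float64) @ w


def make_gaussian_kernel(spec: GaussianKernelSpec) -> np.ndarray:
    """Sample the continuous Gaussian on the kernel grid and renormalize.

    The 1/(2*pi*sigma^2) prefactor cancels in the renormalization.
    """
    r = spec.size // 2
    ax = np.arange(-r, r + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * spec.sigma ** 2))
    return k / k.sum()


def blend(gray: np.ndarray, spec: GaussianKernelSpec) -> np.ndarray:
    """2-D convolution with the normalized Gaussian, reflect-padded borders."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ChannelCountError(f"expected a 2-D gray image, got shape {gray.shape}")
    if spec.size > min(gray.shape):
        raise SizeError(f"kernel side {spec.size} exceeds image extent {gray.shape}")
    kernel = make_gaussian_kernel(spec)
    # symmetric kernel: correlation equals convolution
    return ndimage.correlate(gray, kernel, mode="mirror")


def gamma_correct(gray: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law remap ``(v/255)^(1/gamma) * 255``; fixes 0 and 255."""
    if gamma <= 0:
        raise ParameterError(f"gamma must be positive, got {gamma}")
    gray = np.asarray(gray, dtype=np.float64)
    return np.clip(gray / 255.0, 0.0, 1.0) ** (1.0 / gamma) * 255.0


def select_gamma(gray: np.ndarray, policy: GammaPolicy) -> float:
    """Dark images (mean below threshold) get ``gamma_dark``; tie counts as light."""
    return policy.gamma_dark if float(np.mean(gray)) < policy.luminance_threshold else policy.gamma_light


def dodge(gray: np.ndarray, blended: np.ndarray) -> np.ndarray:
    """Color-dodge of the grayscale by the inverted blend: gray*255/blend."""
    return np.clip(gray * 255.0 / np.maximum(blended, 1.0), 0.0, 255.0)


def run_cat(img: np.ndarray, params: CatParams | None = None) -> np.ndarray:
    """Full CAT pipeline: grayscale -> blend -> (dodge) -> gamma correction."""
    params = params or CatParams()
    gray = to_grayscale(img)
    blended = blend(gray, params.kernel)
    pre = dodge(gray, blended) if params.dodge_blend else blended
    gamma = select_gamma(pre, params.gamma_policy)
    return gamma_correct(pre, gamma)


def quantize(img: np.ndarray) -> np.ndarray:
    """Round-half-up and clip to [0, 255]; used only at file output."""
    return np.clip(np.floor(np.asarray(img, dtype=np.float64) + 0.5), 0, 255).astype(np.uint8)
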