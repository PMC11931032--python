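"""Differentiable structural similarity for use as a training loss.

Implements the windowed SSIM of Wang et al. (11x11 Gaussian window,
sigma = 1.5, stabilizers C1 = (0.01 L)^2, C2 = (0.03 L)^2 with L = 255)
inside the autodiff engine so its gradient can drive the sketch-to-photo
generator.  Statistics use population (uniformly weighted) moments and
the mean is taken over valid window positions only, matching the
evaluation-side SSIM in :mod:`catdeblur.metrics` to float tolerance.
"""
from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

_WIN = 11
_SIGMA = 1.5
_C1 = (0.01 * 255.0) ** 2
_C2 = (0.03 * 255.0) ** 2


def _window1d() -> np.ndarray:
    r = _WIN // 2
    ax = np.arange(-r, r + 1, dtype=np.float64)
    k1 = np.exp(-(ax ** 2) / (2 * _SIGMA ** 2))
    return k1 / k1.sum()


_W1 = _window1d()


def _filter(x: Tensor) -> Tensor:
    """Valid-mode Gaussian filtering of a (B, C, H, W) tensor, per channel.

    The 2-D Gaussian window separates into two 1-D passes, which keeps
    the im2col expansion small.
    """
    B, C, H, W = x.shape
    xr = ad.reshape(x, (B * C, 1, H, W))
    w = Tensor(_W1.reshape(1, _WIN).astype(x.dtype))
    Ho, Wo = H - _WIN + 1, W - _WIN + 1

    colsh = ad.im2col_axis(xr, _WIN, axis=3)            # B*C,1,WIN,H,Wo
    colsh = ad.reshape(colsh, (B * C, _WIN, H * Wo))
    hpass = ad.matmul(w, colsh)                          # B*C,1,H*Wo
    hpass = ad.reshape(hpass, (B * C, 1, H, Wo))

    colsv = ad.im2col_axis(hpass, _WIN, axis=2)          # B*C,1,WIN,Ho,Wo
    colsv = ad.reshape(colsv, (B * C, _WIN, Ho * Wo))
    vpass = ad.matmul(w, colsv)
    return ad.reshape(vpass, (B, C, Ho, Wo))


def ssim_graph(x: Tensor, y: Tensor) -> Tensor:
    """Mean SSIM between two (B, C, H, W) tensors with values in [-1, 1]."""
    x255 = ad.mul(ad.add(x, 1.0), 127.5)
    y255 = ad.mul(ad.add(y, 1.0), 127.5)
    mx = _filter(x255)
    my = _filter(y255)
    mxx = _filter(ad.mul(x255, x255))
    myy = _filter(ad.mul(y255, y255))
    mxy = _filter(ad.mul(x255, y255))
    vx = ad.add(mxx, -ad.mul(mx, mx))
    vy = ad.add(myy, -ad.mul(my, my))
    cxy = ad.add(mxy, -ad.mul(mx, my))
    num = ad.mul(ad.add(ad.mul(ad.mul(mx, my), 2.0), _C1),
                 ad.add(ad.mul(cxy, 2.0), _C2))
    den = ad.mul(ad.add(ad.add(ad.mul(mx, mx), ad.mul(my, my)), _C1),
                 ad.add(ad.add(vx, vy), _C2))
    return ad.tmean(ad.mul(num, ad.power(den, -1.0)))
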