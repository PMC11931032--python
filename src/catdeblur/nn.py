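"""Network building blocks (modules, layers, Adam) over the autodiff engine.

Layout convention is NCHW.  All parameter initialization draws from a
caller-supplied :class:`numpy.random.Generator`, so two builds with equal
seeds are bit-identical.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Minimal module: parameter discovery by attribute traversal."""

    def __init__(self):
        self.training = True

    def __call__(self, x):
        return self.forward(x)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    # -- serialization -------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: np.array(p.data) for name, p in self.named_parameters()}
        for name, buf in self._named_buffers():
            state[name] = np.array(buf)
        return state

    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child._named_buffers(prefix + name + ".")

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.array(state[name], dtype=p.dtype)
        for name, _ in list(self._named_buffers()):
            *path, attr = name.split(".")
            obj = self
            for part in path:
                obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
            setattr(obj, attr, np.array(state[name]))


def save_checkpoint(module: Module, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **module.state_dict())
    if meta is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(meta, indent=2, default=str))


def load_checkpoint(module: Module, path) -> Module:
    with np.load(Path(path), allow_pickle=False) as data:
        module.load_state_dict({k: data[k] for k in data.files})
    return module


class Sequential(Module):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he_normal(rng: np.random.Generator, shape, fan_in: int, scale: float = 1.0):
    std = scale * np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


def _as_pair(pad):
    """Normalize a pad spec to ((top, bottom), (left, right))."""
    if isinstance(pad, int):
        return (pad, pad), (pad, pad)
    (a, b), (c, d) = pad
    return (a, b), (c, d)


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None, bias=True, w_scale=1.0):
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = _as_pair(pad)
        self.weight = Tensor(_he_normal(rng, (cout, cin, k, k), cin * k * k, w_scale),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        (pt, pb), (pl, pr) = self.pad
        if pt or pb or pl or pr:
            x = ad.pad_zero(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        B = x.shape[0]
        H, W = x.shape[-2:]
        Ho = (H - self.k) // self.stride + 1
        Wo = (W - self.k) // self.stride + 1
        cols = ad.im2col(x, self.k, self.stride)                       # B,C,k,k,Ho,Wo
        cols = ad.reshape(cols, (B, self.cin * self.k * self.k, Ho * Wo))
        w = ad.reshape(self.weight, (self.cout, self.cin * self.k * self.k))
        out = ad.matmul(w, cols)                                        # B,cout,Ho*Wo
        out = ad.reshape(out, (B, self.cout, Ho, Wo))
        if self.bias is not None:
            out = ad.add(out, ad.reshape(self.bias, (1, self.cout, 1, 1)))
        return out


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, k, stride=2, pad=1, output_padding=0, rng=None,
                 bias=True, w_scale=1.0):
        super().__init__()
        if output_padding > pad:
            raise ValueError("output_padding must not exceed pad")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.p, self.op = stride, pad, output_padding
        self.weight = Tensor(_he_normal(rng, (cin, cout, k, k), cin * k * k, w_scale),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        B = x.shape[0]
        H, W = x.shape[-2:]
        Hf = (H - 1) * self.stride + self.k
        Wf = (W - 1) * self.stride + self.k
        w = ad.reshape(self.weight, (self.cin, self.cout * self.k * self.k))
        wT = ad.transpose(w, (1, 0))
        xr = ad.reshape(x, (B, self.cin, H * W))
        cols = ad.matmul(wT, xr)                                        # B,cout*k*k,H*W
        cols = ad.reshape(cols, (B, self.cout, self.k, self.k, H, W))
        full = ad.col2im(cols, self.k, self.stride, Hf, Wf)             # B,cout,Hf,Wf
        key = (slice(None), slice(None),
               slice(self.p, Hf - self.p + self.op),
               slice(self.p, Wf - self.p + self.op))
        out = ad.getslice(full, key)
        if self.bias is not None:
            out = ad.add(out, ad.reshape(self.bias, (1, self.cout, 1, 1)))
        return out


class Dense(Module):
    def __init__(self, cin, cout, rng=None, w_scale=1.0):
        super().__init__()
        self.weight = Tensor(_he_normal(rng, (cin, cout), cin, w_scale), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        if x.ndim > 2:
            x = ad.reshape(x, (x.shape[0], int(np.prod(x.shape[1:]))))
        return ad.add(ad.matmul(x, self.weight), ad.reshape(self.bias, (1, -1)))


class BatchNorm2d(Module):
    """Batch normalization with Keras-style running-average momentum."""

    def __init__(self, c, momentum=0.999, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones((1, c, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1), dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros((1, c, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, c, 1, 1), dtype=np.float32)

    def forward(self, x):
        if self.training:
            mu = ad.tmean(x, axis=(0, 2, 3), keepdims=True)
            var = ad.tmean(ad.mul(ad.add(x, -mu), ad.add(x, -mu)), axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.astype(np.float32)
            self.running_var = m * self.running_var + (1 - m) * var.data.astype(np.float32)
        else:
            mu, var = Tensor(self.running_mean), Tensor(self.running_var)
        xn = ad.mul(ad.add(x, -mu), ad.power(ad.add(var, self.eps), -0.5))
        return ad.add(ad.mul(xn, self.gamma), self.beta)


class InstanceNorm2d(Module):
    def __init__(self, c, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones((1, c, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1), dtype=np.float32), requires_grad=True)

    def forward(self, x):
        mu = ad.tmean(x, axis=(2, 3), keepdims=True)
        var = ad.tmean(ad.mul(ad.add(x, -mu), ad.add(x, -mu)), axis=(2, 3), keepdims=True)
        xn = ad.mul(ad.add(x, -mu), ad.power(ad.add(var, self.eps), -0.5))
        return ad.add(ad.mul(xn, self.gamma), self.beta)


class Identity(Module):
    def forward(self, x):
        return x


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return ad.leaky_relu(x, self.slope)


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class Tanh(Module):
    def forward(self, x):
        return ad.tanh(x)


def make_norm(kind: str, c: int, bn_momentum: float = 0.999) -> Module:
    if kind == "batch":
        return BatchNorm2d(c, momentum=bn_momentum)
    if kind == "instance":
        return InstanceNorm2d(c)
    if kind == "none":
        return Identity()
    raise ValueError(f"unknown norm kind: {kind!r}")


class Adam:
    def __init__(self, params, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
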