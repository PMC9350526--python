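"""Neural-network layers, parameter containers and the Adam optimizer.

Thin module system over :mod:`cmbcascade.autograd`: layers own Parameters,
compose into Modules, and are saved/loaded as named-array checkpoints with a
spec fingerprint so mismatched architectures refuse to load.
"""

from __future__ import annotations

import json
import zlib

import numpy as np

from .autograd import Tensor, batchnorm2d, conv2d, maxpool2x2, upsample_bilinear2x

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "BatchNorm2d", "ReLU",
    "Sigmoid", "MaxPool2d", "UpsampleBilinear2x", "GlobalAvgPool", "Adam",
    "save_checkpoint", "load_checkpoint",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class: recursive parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(prefix=full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.named_buffers(prefix=full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{full}.{i}.")
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                yield full, v

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({name: b.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                own[name].data = arr.astype(own[name].data.dtype, copy=True)
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unexpected key {name}")
        missing = set(own) | set(bufs)
        missing -= set(state)
        if missing:
            raise KeyError(f"missing keys: {sorted(missing)}")


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """3×3 / 1×1 convolution with He-normal initialization."""

    def __init__(self, cin, cout, kernel=3, stride=1, padding=0, dilation=1,
                 bias=True, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (cout, cin, kernel, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, channels, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x):
        c = self.gamma.data.shape[0]
        if self.training:
            out, mu, var = batchnorm2d(x, self.gamma, self.beta, eps=self.eps)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return out
        mu = self.running_mean.reshape(1, c, 1, 1)
        ivar = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, c, 1, 1)
        g = self.gamma.reshape(1, c, 1, 1) * Tensor(ivar)
        b = self.beta.reshape(1, c, 1, 1)
        return (x - Tensor(mu)) * g + b


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class MaxPool2d(Module):
    def forward(self, x):
        return maxpool2x2(x)


class UpsampleBilinear2x(Module):
    def forward(self, x):
        return upsample_bilinear2x(x)


class GlobalAvgPool(Module):
    """Spatial mean, kept as a (N, C, 1, 1) map for broadcasting."""

    def forward(self, x):
        return x.mean(axis=(2, 3), keepdims=True)


class Adam:
    """Adam with the stated defaults: lr 2e-4, betas (0.9, 0.999), no decay."""

    def __init__(self, params, lr=2e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# -- checkpoints ---------------------------------------------------------------

def _fingerprint(spec: dict) -> str:
    payload = json.dumps(spec, sort_keys=True, default=str)
    return f"{zlib.crc32(payload.encode()):08x}"


def save_checkpoint(path, model: Module, spec: dict) -> None:
    """Write named parameter/buffer arrays plus an architecture fingerprint."""
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["__spec__"] = np.frombuffer(
        json.dumps(spec, sort_keys=True, default=str).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, model: Module, spec: dict) -> None:
    """Load a checkpoint, refusing if the stored spec does not match."""
    with np.load(path) as z:
        stored = json.loads(bytes(z["__spec__"]).decode())
        if _fingerprint(stored) != _fingerprint(spec):
            raise ValueError(
                f"checkpoint spec mismatch: stored {stored} != requested {spec}")
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model.load_state_dict(state)
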