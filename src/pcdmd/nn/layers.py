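"""Layer modules built on the tape autograd: Conv3d, BatchNorm3d, pooling,
transposed convolution and scalar skip gates, with named parameters so
training phases can freeze whole encoder scales by name prefix."""

from __future__ import annotations

import numpy as np

from . import tape
from .tape import Tensor


class Module:
    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Tensor] = {}
        self.training = True

    def add_module(self, name: str, mod: "Module") -> "Module":
        self._modules[name] = mod
        return mod

    def add_param(self, name: str, t: Tensor) -> Tensor:
        self._params[name] = t
        return t

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self):
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, mod in self._named_modules():
            if isinstance(mod, BatchNorm3d):
                out[name + ".running_mean"] = mod.running_mean.copy()
                out[name + ".running_var"] = mod.running_var.copy()
        return out

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for name, mod in self._named_modules():
            if isinstance(mod, BatchNorm3d):
                mod.running_mean = state[name + ".running_mean"].copy()
                mod.running_var = state[name + ".running_var"].copy()

    def _named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for mname, mod in self._modules.items():
            yield from mod._named_modules(prefix + mname + ".")


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, kernel=(3, 3, 3), pad=None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kd, kh, kw = kernel
        fan_in = cin * kd * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kd, kh, kw))
        self.w = self.add_param("w", Tensor(w.astype(np.float32), requires_grad=True))
        self.b = self.add_param("b", Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True))
        self.pad = pad if pad is not None else (kd // 2, kh // 2, kw // 2)

    def __call__(self, x: Tensor) -> Tensor:
        return tape.conv3d(x, self.w, self.b, self.pad)


class BatchNorm3d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = self.add_param("gamma", Tensor(np.ones(c, dtype=np.float32), requires_grad=True))
        self.beta = self.add_param("beta", Tensor(np.zeros(c, dtype=np.float32), requires_grad=True))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.track_stats = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, (m, v) = tape.batchnorm(x, self.gamma, self.beta, self.eps, running=None)
            if self.track_stats:
                mom = self.momentum
                self.running_mean = ((1 - mom) * self.running_mean + mom * m).astype(np.float32)
                self.running_var = ((1 - mom) * self.running_var + mom * v).astype(np.float32)
            return out
        out, _ = tape.batchnorm(
            x, self.gamma, self.beta, self.eps, running=(self.running_mean, self.running_var)
        )
        return out


class MaxPool3d(Module):
    """Spatial-only (1, 2, 2) pooling: the bin axis is never collapsed."""

    def __call__(self, x: Tensor) -> Tensor:
        return tape.maxpool_spatial(x)


class ConvTranspose3d(Module):
    """Spatial (1, 2, 2) up-convolution with stride (1, 2, 2)."""

    def __init__(self, cin: int, cout: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout, 2, 2))
        self.w = self.add_param("w", Tensor(w.astype(np.float32), requires_grad=True))
        self.b = self.add_param("b", Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        return tape.conv_transpose_spatial(x, self.w, self.b)


class SkipGate(Module):
    """Learnable scalar gate on a skip connection, initialized at 1."""

    def __init__(self):
        super().__init__()
        self.g = self.add_param("g", Tensor(np.ones((), dtype=np.float32), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        return tape.scale(x, self.g)
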