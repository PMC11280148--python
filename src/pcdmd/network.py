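"""MD-Unet: a 3D encoder-decoder over the bin-stacked volume, with the
customized focal + mean-gradient-error loss.

The three co-registered bin images are stacked into a (1, 3, H, W) volume
(one channel, bin depth 3).  Convolutions are 3D with 'same' padding so the
bin depth stays 3 at every scale; pooling and up-convolution act spatially
only.  Skip connections at every scale carry encoder features to the decoder;
on the first and second scales they pass through learnable scalar gates
(initialized at 1).  A bin-collapsing projection (kernel spanning the full
bin depth, 1x1 spatially) maps to one channel per material, followed by a
softmax so every pixel's class probabilities sum to one.

Loss (defaults): ``total = focal + 0.01 * mge`` where the focal term is
``-(1/N) sum_i w_i (1 - p_i)^gamma t_i log p_i`` with gamma = 2 and a reduced
background weight, and the mean gradient error compares squared Sobel
gradient-magnitude fields of prediction and ground truth per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import tape
from .nn.layers import BatchNorm3d, Conv3d, ConvTranspose3d, MaxPool3d, Module, SkipGate
from .nn.tape import Tensor
from .phantom import CLASS_NAMES

__all__ = [
    "NetworkConfig",
    "LossConfig",
    "MDUnet",
    "build_network",
    "count_hidden_layers",
    "focal_loss",
    "mge_loss",
    "total_loss",
    "one_hot",
    "SOBEL_H",
    "SOBEL_V",
]

SOBEL_H = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_V = SOBEL_H.T.copy()


@dataclass(frozen=True)
class NetworkConfig:
    n_scales: int = 5
    convs_per_block: int = 2
    base_channels: int = 64
    n_materials: int = 4
    weighted_skip_scales: tuple = (1, 2)
    bin_depth: int = 3

    def channels(self, scale: int) -> int:
        """Channels at 1-based scale k: base * 2**(k-1)."""
        return self.base_channels * 2 ** (scale - 1)

    @classmethod
    def desk(cls) -> "NetworkConfig":
        """Reduced net for CPU-scale experiments."""
        return cls(n_scales=3, base_channels=16)


@dataclass(frozen=True)
class LossConfig:
    gamma: float = 2.0
    w_b: float = 0.25  # background class weight
    lam: float = 0.01  # MGE scale
    sobel_h: np.ndarray = field(default_factory=lambda: SOBEL_H.copy(), compare=False, repr=False)
    sobel_v: np.ndarray = field(default_factory=lambda: SOBEL_V.copy(), compare=False, repr=False)
    clamp_floor: float = 1e-7

    def __post_init__(self):
        if self.gamma < 0 or self.lam < 0 or self.w_b <= 0:
            raise ValueError("invalid loss configuration")

    def class_weights(self, n_classes: int) -> np.ndarray:
        w = np.ones(n_classes)
        w[0] = self.w_b
        return w


class MDUnet(Module):
    def __init__(self, config: NetworkConfig = NetworkConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        S = config.n_scales
        ch = [1] + [config.channels(k) for k in range(1, S + 1)]
        for k in range(1, S + 1):
            cin = ch[k - 1]
            for j in range(config.convs_per_block):
                self.add_module(f"enc{k}.conv{j}", Conv3d(cin if j == 0 else ch[k], ch[k], rng=rng))
                self.add_module(f"enc{k}.bn{j}", BatchNorm3d(ch[k]))
            if k < S:
                self.add_module(f"pool{k}", MaxPool3d())
        for k in range(S - 1, 0, -1):
            self.add_module(f"up{k}", ConvTranspose3d(ch[k + 1], ch[k], rng=rng))
            for j in range(config.convs_per_block):
                cin = 2 * ch[k] if j == 0 else ch[k]
                self.add_module(f"dec{k}.conv{j}", Conv3d(cin, ch[k], rng=rng))
                self.add_module(f"dec{k}.bn{j}", BatchNorm3d(ch[k]))
        for k in config.weighted_skip_scales:
            if k < S:
                self.add_module(f"gate{k}", SkipGate())
        self.add_module(
            "head",
            Conv3d(ch[1], config.n_materials, kernel=(config.bin_depth, 1, 1), pad=(0, 0, 0), rng=rng),
        )

    # -- forward -----------------------------------------------------------
    def _block(self, prefix: str, x: Tensor) -> Tensor:
        for j in range(self.config.convs_per_block):
            x = self._modules[f"{prefix}.conv{j}"](x)
            x = self._modules[f"{prefix}.bn{j}"](x)
            x = tape.relu(x)
        return x

    def forward(self, image) -> Tensor:
        """Bin stack (3, H, W) or (1, 3, H, W) -> class probabilities (C, H, W)."""
        x = image if isinstance(image, Tensor) else Tensor(np.asarray(image, dtype=np.float32))
        if x.data.ndim == 3:
            x = tape.reshape(x, (1,) + x.data.shape)
        if x.data.shape[1] != self.config.bin_depth:
            raise ValueError(f"expected bin depth {self.config.bin_depth}")
        S = self.config.n_scales
        H, W = x.data.shape[2:]
        m = 2 ** (S - 1)
        pad_h, pad_w = (-H) % m, (-W) % m
        if pad_h or pad_w:
            x = Tensor(np.pad(x.data, ((0, 0), (0, 0), (0, pad_h), (0, pad_w))),
                       requires_grad=x.requires_grad, parents=(x,),
                       backward=(lambda g, _x=x, _H=H, _W=W: tape._acc(_x, g[:, :, :_H, :_W]))
                       if x.requires_grad else None)
        skips = {}
        for k in range(1, S + 1):
            x = self._block(f"enc{k}", x)
            if k < S:
                skips[k] = x
                x = self._modules[f"pool{k}"](x)
        for k in range(S - 1, 0, -1):
            x = self._modules[f"up{k}"](x)
            skip = skips[k]
            if f"gate{k}" in self._modules:
                skip = self._modules[f"gate{k}"](skip)
            x = tape.concat(skip, x, axis=0)
            x = self._block(f"dec{k}", x)
        x = self._modules["head"](x)  # (n_materials, 1, H', W')
        x = tape.reshape(x, (x.data.shape[0],) + x.data.shape[2:])
        if pad_h or pad_w:
            data = x.data[:, :H, :W]
            x = Tensor(data, requires_grad=x.requires_grad, parents=(x,),
                       backward=(lambda g, _x=x, _s=x.data.shape: tape._acc(
                           _x, np.pad(g, ((0, 0), (0, pad_h), (0, pad_w)))))
                       if x.requires_grad else None)
        return tape.softmax(x, axis=0)

    __call__ = forward

    def frozen_param_names(self, scales=(1,)) -> set:
        """Parameter names of the given encoder scales (freeze contract)."""
        return {
            name
            for name, _ in self.named_parameters()
            if any(name.startswith(f"enc{k}.") for k in scales)
        }


def build_network(config: NetworkConfig = NetworkConfig(), seed: int = 0) -> MDUnet:
    return MDUnet(config, seed)


def count_hidden_layers(network: MDUnet) -> int:
    """Hidden-layer audit under the documented convention.

    Counted: every convolution, pooling layer, up-convolution, weighted-skip
    gate, and the output projection.  Batch-normalization and activation
    layers are not counted.  The default configuration audits to 29.
    """
    S = network.config.n_scales
    cpb = network.config.convs_per_block
    gates = sum(1 for name in network._modules if name.startswith("gate"))
    return cpb * S + (S - 1) + (S - 1) + cpb * (S - 1) + gates + 1


# ---------------------------------------------------------------------------
# losses


def one_hot(label_map: np.ndarray, n_classes: int = len(CLASS_NAMES)) -> np.ndarray:
    """Label map (H, W) -> one-hot stack (n_classes, H, W), float."""
    return (np.arange(n_classes)[:, None, None] == label_map[None]).astype(np.float64)


def _validate(f_p, f_gt):
    if f_p.shape != f_gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    s = f_p.sum(axis=0)
    if np.any(f_p < -1e-6) or np.any(np.abs(s - 1.0) > 1e-5):
        raise ValueError("prediction is not a per-pixel simplex")


def focal_loss(f_p, f_gt_onehot: np.ndarray, config: LossConfig = LossConfig()):
    """Background-weighted focal loss; returns a Tensor for Tensor input."""
    tensor_in = isinstance(f_p, Tensor)
    if not tensor_in:
        _validate(np.asarray(f_p), f_gt_onehot)
        f_p = Tensor(np.asarray(f_p, dtype=np.float64))
    n_classes = f_p.data.shape[0]
    n_pix = f_p.data[0].size
    w = config.class_weights(n_classes)[:, None, None]
    mask = f_gt_onehot * w  # only true-class terms survive
    p = tape.clamp(f_p, config.clamp_floor, 1.0)
    term = tape.mul(tape.mul(power(1.0 - p, config.gamma), tape.log(p)), -mask)

    out = tape.mul(term.sum(), 1.0 / n_pix)
    return out if tensor_in else float(out.data)


def power(x, p):
    # (1 - p)^gamma with gamma possibly 0; works on Tensor
    return tape.power(x, p) if p != 0 else Tensor(np.ones_like(x.data))


def _grad_mag_sq(x, kh, kv):
    gh = tape.conv2d_fixed(x, kh)
    gv = tape.conv2d_fixed(x, kv)
    return tape.add(tape.power(gh, 2.0), tape.power(gv, 2.0))


def mge_loss(f_p, f_gt_onehot: np.ndarray, config: LossConfig = LossConfig()):
    """Mean gradient error between Sobel gradient-magnitude-squared fields."""
    tensor_in = isinstance(f_p, Tensor)
    if not tensor_in:
        if np.asarray(f_p).shape != f_gt_onehot.shape:
            raise ValueError("prediction and ground truth shapes differ")
        f_p = Tensor(np.asarray(f_p, dtype=np.float64))
    n_pix = f_p.data[0].size
    gt = Tensor(np.asarray(f_gt_onehot, dtype=f_p.data.dtype))
    g_gt = _grad_mag_sq(gt, config.sobel_h, config.sobel_v)
    g_p = _grad_mag_sq(f_p, config.sobel_h, config.sobel_v)
    diff = tape.power(tape.add(g_gt, tape.mul(g_p, -1.0)), 2.0)
    out = tape.mul(diff.sum(), 1.0 / n_pix)
    return out if tensor_in else float(out.data)


def total_loss(f_p, f_gt_onehot: np.ndarray, config: LossConfig = LossConfig()):
    """Customized loss: focal + lambda * MGE."""
    fl = focal_loss(f_p, f_gt_onehot, config)
    if config.lam == 0:
        return fl
    mge = mge_loss(f_p, f_gt_onehot, config)
    if isinstance(f_p, Tensor):
        return tape.add(fl, tape.mul(mge, config.lam))
    return fl + config.lam * mge
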