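"""Two-phase transfer-learning protocol for MD-Unet.

Pre-training runs on simulated (calibration-corrected) scans with flips,
random rotation and elastic deformation; fine-tuning runs on real-domain
scans with the first encoder scale frozen and elastic deformation disabled
(real data carry artifacts and noise; only rigid augmentations are safe).
The full protocol is 50 pre-training and 100 fine-tuning epochs at batch
size 1 with Adam at 1e-5; the desk preset scales those down for CPU work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .network import LossConfig, MDUnet, focal_loss, mge_loss, one_hot
from .nn import tape
from .nn.optim import Adam
from .simulator import MultiBinImage

__all__ = [
    "TrainConfig",
    "DatasetManifest",
    "augment_pretrain",
    "augment_finetune",
    "pretrain",
    "finetune",
    "predict",
]


@dataclass(frozen=True)
class TrainConfig:
    pretrain_epochs: int = 50
    finetune_epochs: int = 100
    batch_size: int = 1
    learning_rate: float = 1e-5
    freeze_scales_finetune: tuple = (1,)
    seed: int = 0
    augment_pretrain: bool = True
    augment_finetune: bool = True
    elastic_grid: int = 8  # control points per axis
    elastic_max_px: float = 8.0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.pretrain_epochs < 1 or self.finetune_epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    @classmethod
    def desk(cls) -> "TrainConfig":
        """CPU-scale protocol: fewer epochs, a workable step size at those
        step counts, and an elastic cap proportional to the 64-pixel grid."""
        return cls(pretrain_epochs=10, finetune_epochs=20, learning_rate=1e-3,
                   elastic_max_px=2.0)


@dataclass(frozen=True)
class DatasetManifest:
    """Paired (image, label) samples for one training phase."""

    samples: tuple  # of (MultiBinImage, ndarray labels)
    phase: str  # pretrain | finetune | validation

    def __post_init__(self):
        if self.phase not in ("pretrain", "finetune", "validation"):
            raise ValueError("unknown phase")
        for img, lab in self.samples:
            if img.data.shape[1:] != lab.shape:
                raise ValueError("image and labels are not co-registered")
            if self.phase == "pretrain" and img.domain != "simulated":
                raise ValueError("pretrain manifest must contain simulated-domain images")
            if self.phase == "finetune" and img.domain != "real_emulated":
                raise ValueError("finetune manifest must contain real-emulated images")

    def __len__(self):
        return len(self.samples)


# ---------------------------------------------------------------------------
# augmentation


def _elastic_field(shape, rng, grid_pts: int, max_px: float):
    n = shape[0]
    coarse = rng.normal(0.0, 1.0, size=(2, grid_pts, grid_pts))
    coarse = ndimage.gaussian_filter(coarse, sigma=(0, 1.0, 1.0))
    disp = np.stack(
        [ndimage.zoom(coarse[k], n / grid_pts, order=1, mode="nearest") for k in range(2)]
    )
    peak = np.abs(disp).max()
    if peak > 0:
        disp *= max_px / peak * rng.random()  # random strength up to the cap
    return disp


def _apply_transform(image: np.ndarray, labels: np.ndarray, rng,
                     elastic: bool, grid_pts: int, max_px: float):
    """One shared transform for the 3 bins and the labels."""
    img = image.copy()
    lab = labels.copy()
    if rng.random() < 0.5:
        img = img[:, :, ::-1]
        lab = lab[:, ::-1]
    if rng.random() < 0.5:
        img = img[:, ::-1, :]
        lab = lab[::-1, :]
    angle = rng.uniform(0.0, 360.0)
    img = np.stack(
        [ndimage.rotate(b, angle, reshape=False, order=1, mode="constant", cval=0.0) for b in img]
    )
    lab = ndimage.rotate(lab, angle, reshape=False, order=0, mode="constant", cval=0)
    if elastic:
        disp = _elastic_field(lab.shape, rng, grid_pts, max_px)
        n = lab.shape[0]
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        coords = np.stack([ii + disp[0], jj + disp[1]])
        img = np.stack(
            [ndimage.map_coordinates(b, coords, order=1, mode="constant", cval=0.0) for b in img]
        )
        lab = ndimage.map_coordinates(lab, coords, order=0, mode="constant", cval=0)
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def augment_pretrain(image, labels, rng, config: TrainConfig = TrainConfig()):
    """Flips, free rotation and elastic deformation (simulation phase)."""
    if not config.augment_pretrain:
        return image, labels
    return _apply_transform(image, labels, rng, True, config.elastic_grid, config.elastic_max_px)


def augment_finetune(image, labels, rng, config: TrainConfig = TrainConfig()):
    """Flips and free rotation only; elastic deformation is always off here."""
    if not config.augment_finetune:
        return image, labels
    return _apply_transform(image, labels, rng, False, config.elastic_grid, config.elastic_max_px)


# ---------------------------------------------------------------------------
# training


class NaNLossError(RuntimeError):
    pass


def _run_phase(network: MDUnet, manifest: DatasetManifest, epochs: int, config: TrainConfig,
               rng, augment_fn, frozen_names: set):
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    params = [p for name, p in network.named_parameters() if name not in frozen_names]
    opt = Adam(params, lr=config.learning_rate)
    for name, mod in network._named_modules():
        from .nn.layers import BatchNorm3d

        if isinstance(mod, BatchNorm3d) and any(n.startswith(name + ".") for n in frozen_names):
            mod.track_stats = False
    network.train(True)
    history = []
    n_classes = network.config.n_materials
    for epoch in range(epochs):
        order = rng.permutation(len(manifest))
        fl_sum = mge_sum = 0.0
        for idx in order:
            img, lab = manifest.samples[int(idx)]
            data, lab_a = augment_fn(img.data, lab, rng, config)
            onehot = one_hot(lab_a, n_classes)
            probs = network.forward(data.astype(np.float32))
            fl = focal_loss(probs, onehot, config.loss)
            mge = mge_loss(probs, onehot, config.loss)
            loss = tape.add(fl, tape.mul(mge, config.loss.lam))
            if not np.isfinite(loss.data):
                raise NaNLossError(
                    f"non-finite loss at epoch {epoch}: focal={fl.data}, mge={mge.data}"
                )
            network.zero_grad()
            loss.backward()
            opt.step()
            fl_sum += float(fl.data)
            mge_sum += float(mge.data)
        n = len(manifest)
        history.append(
            {
                "epoch": epoch,
                "focal": fl_sum / n,
                "mge": mge_sum / n,
                "total": (fl_sum + config.loss.lam * mge_sum) / n,
            }
        )
    return history


def pretrain(network: MDUnet, manifest: DatasetManifest, config: TrainConfig = TrainConfig()):
    """Phase 1: the entire model trains on simulated images."""
    if manifest.phase != "pretrain":
        raise ValueError("manifest phase must be 'pretrain'")
    rng = np.random.default_rng(config.seed)
    history = _run_phase(
        network, manifest, config.pretrain_epochs, config, rng,
        augment_pretrain if config.augment_pretrain else _identity_aug, frozen_names=set()
    )
    return network, history


def finetune(network: MDUnet, manifest: DatasetManifest, config: TrainConfig = TrainConfig()):
    """Phase 2: encoder scale 1 frozen; trains on real-domain images."""
    if manifest.phase != "finetune":
        raise ValueError("manifest phase must be 'finetune'")
    rng = np.random.default_rng(config.seed + 1)
    frozen = network.frozen_param_names(config.freeze_scales_finetune)
    history = _run_phase(
        network, manifest, config.finetune_epochs, config, rng,
        augment_finetune if config.augment_finetune else _identity_aug, frozen_names=frozen
    )
    return network, history


def _identity_aug(image, labels, rng, config):
    return image, labels


def predict(network: MDUnet, image: MultiBinImage | np.ndarray):
    """Inference: probability map and categorical map (argmax, low index wins)."""
    data = image.data if isinstance(image, MultiBinImage) else np.asarray(image)
    network.eval()
    probs = network.forward(data.astype(np.float32)).data
    return probs, probs.argmax(axis=0)
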