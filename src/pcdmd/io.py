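"""Persistence: NIfTI image stacks with JSON header extensions, TIFF export,
sinogram archives, phantom specs and network checkpoints."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .network import MDUnet, NetworkConfig
from .phantom import ImageGrid, InsertSpec, PhantomSpec
from .simulator import BinnedSinogram, Geometry, MultiBinImage
from .spectral import EnergyBinSet

__all__ = [
    "save_image",
    "load_image",
    "save_labels",
    "load_labels",
    "save_tiff",
    "save_sinogram",
    "load_sinogram",
    "spec_to_json",
    "spec_from_json",
    "save_checkpoint",
    "load_checkpoint",
]

_EXT_CODE = 6  # NIfTI 'comment' extension


def _meta_ext(meta: dict) -> nib.nifti1.Nifti1Extension:
    return nib.nifti1.Nifti1Extension(_EXT_CODE, json.dumps(meta).encode())


def _read_meta(img: nib.Nifti1Image) -> dict:
    for ext in img.header.extensions:
        try:
            return json.loads(bytes(ext.get_content()).decode())
        except Exception:
            continue
    return {}


def save_image(image: MultiBinImage, path) -> None:
    """3-slice NIfTI volume; pitch/domain/bins in a header extension."""
    vol = np.moveaxis(image.data, 0, -1).astype(np.float32)  # (H, W, bins)
    affine = np.diag([image.pitch_mm, image.pitch_mm, 1.0, 1.0])
    nii = nib.Nifti1Image(vol, affine)
    nii.header.extensions.append(
        _meta_ext({"pitch_mm": image.pitch_mm, "domain": image.domain, "bins": image.bin_set.bins})
    )
    nib.save(nii, str(path))


def load_image(path) -> MultiBinImage:
    nii = nib.load(str(path))
    meta = _read_meta(nii)
    data = np.moveaxis(np.asarray(nii.dataobj, dtype=np.float64), -1, 0)
    return MultiBinImage(
        data=data,
        pitch_mm=float(meta.get("pitch_mm", abs(nii.affine[0, 0]))),
        domain=meta.get("domain", "simulated"),
        bin_set=EnergyBinSet(tuple(map(tuple, meta.get("bins")))) if meta.get("bins") else EnergyBinSet.default(),
    )


def save_labels(labels: np.ndarray, pitch_mm: float, path) -> None:
    nii = nib.Nifti1Image(labels.astype(np.int16), np.diag([pitch_mm, pitch_mm, 1.0, 1.0]))
    nib.save(nii, str(path))


def load_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.int64)


def save_tiff(image: MultiBinImage, path) -> None:
    tifffile.imwrite(str(path), image.data.astype(np.float32))


def save_sinogram(sino: BinnedSinogram, path) -> None:
    np.savez(
        str(path),
        p=sino.p,
        flux_per_bin=sino.flux_per_bin,
        bins=np.array(sino.bin_set.bins),
        geometry=json.dumps(
            {k: v for k, v in asdict(sino.geometry).items() if k != "detector"}
        ),
    )


def load_sinogram(path) -> BinnedSinogram:
    z = np.load(str(path), allow_pickle=False)
    geo = Geometry(**json.loads(str(z["geometry"])))
    return BinnedSinogram(
        p=z["p"], flux_per_bin=z["flux_per_bin"], geometry=geo,
        bin_set=EnergyBinSet(tuple(map(tuple, z["bins"]))),
    )


def spec_to_json(spec: PhantomSpec) -> str:
    return json.dumps(
        {
            "base_radius": spec.base_radius,
            "grid": {"npix": spec.grid.npix, "pitch_mm": spec.grid.pitch_mm},
            "inserts": [asdict(i) for i in spec.inserts],
        }
    )


def spec_from_json(text: str) -> PhantomSpec:
    d = json.loads(text)
    return PhantomSpec(
        base_radius=d["base_radius"],
        inserts=tuple(
            InsertSpec(i["material"], i["concentration"], tuple(i["center"]), i["radius"])
            for i in d["inserts"]
        ),
        grid=ImageGrid(d["grid"]["npix"], d["grid"]["pitch_mm"]),
    )


def save_checkpoint(network: MDUnet, path) -> None:
    """Weights plus the embedded network configuration."""
    state = network.state_dict()
    np.savez(str(path), __config__=json.dumps(asdict(network.config)), **state)


def load_checkpoint(path) -> MDUnet:
    z = np.load(str(path), allow_pickle=False)
    cfg = json.loads(str(z["__config__"]))
    cfg["weighted_skip_scales"] = tuple(cfg["weighted_skip_scales"])
    net = MDUnet(NetworkConfig(**cfg))
    net.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
    return net
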