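"""End-to-end experiment driver: simulate -> calibrate -> pretrain ->
finetune -> decompose -> evaluate, with deterministic seeding, persisted
intermediates and a machine-readable provenance record.

Two presets are provided.  ``full_protocol`` mirrors the documented
acquisition/training protocol (87 pre-training and 16 fine-tuning image sets,
50/100 epochs, 1440-view fan geometry, lr 1e-5, full-size network).  ``desk``
is the CPU-scale configuration used by the test suite: 64-pixel grids,
120-view parallel geometry, a 3-scale / 16-channel network, 10/20 epochs at
lr 1e-3.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .baselines import md_ls, md_tv, to_categorical
from .calibration import apply_calibration, extract_pairs, fit_per_bin
from .metrics import MetricsReport, evaluate, miou
from .network import LossConfig, NetworkConfig, build_network
from .phantom import ImageGrid, PhantomSpec, reference_phantom, sample_phantom
from .simulator import GapConfig, Geometry, emulate_real_domain, simulate_scan
from .spectral import basis_matrix, build_spectrum
from .train import DatasetManifest, TrainConfig, finetune, predict, pretrain

__all__ = ["ExperimentConfig", "run_experiment", "desk_benchmark", "make_fixtures"]


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    kvp: float = 140.0
    hvl_mm_al: float = 10.0
    npix: int = 64
    n_views: int = 120
    fov_mm: float = 250.0
    flux: float = 4e5
    n_pretrain: int = 30
    n_finetune: int = 8
    n_holdout: int = 3
    gap: GapConfig = field(default_factory=GapConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig.desk)
    train: TrainConfig = field(default_factory=TrainConfig.desk)
    tv_beta: float = 0.02
    methods: tuple = ("md_ls", "md_tv", "unet", "md_unet")
    preset: str = "desk"

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "ExperimentConfig":
        return cls(seed=seed, **overrides)

    @classmethod
    def full_protocol(cls, seed: int = 0) -> "ExperimentConfig":
        """The documented full protocol (hours of CPU time; not the default)."""
        return cls(
            seed=seed, npix=256, n_views=1440, n_pretrain=87, n_finetune=16,
            n_holdout=4, network=NetworkConfig(), train=TrainConfig(), preset="full_protocol",
        )

    def to_yaml(self) -> str:
        d = asdict(self)
        d["train"]["loss"].pop("sobel_h", None)
        d["train"]["loss"].pop("sobel_v", None)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text)
        d["gap"] = GapConfig(**d["gap"])
        d["network"] = NetworkConfig(**{**d["network"], "weighted_skip_scales": tuple(d["network"]["weighted_skip_scales"])})
        loss = LossConfig(**d["train"].pop("loss"))
        d["train"] = TrainConfig(**{**d["train"], "freeze_scales_finetune": tuple(d["train"]["freeze_scales_finetune"]), "loss": loss})
        d["methods"] = tuple(d["methods"])
        return cls(**d)

    def fingerprint(self) -> dict:
        return {
            "config_sha256": hashlib.sha256(self.to_yaml().encode()).hexdigest(),
            "seed": self.seed,
            "pcdmd_version": __version__,
            "numpy_version": np.__version__,
        }


def _build_dataset(config: ExperimentConfig):
    """Deterministic dataset construction shared by the driver and benchmark."""
    seed = config.seed
    grid = ImageGrid(config.npix, config.fov_mm / config.npix)
    geometry = Geometry.desk(config.npix, config.n_views, config.fov_mm) \
        if config.preset == "desk" else Geometry(
            mode="parallel", fov=config.fov_mm, n_views=config.n_views, detector_rows=config.npix)
    spectrum = build_spectrum(config.kvp, config.hvl_mm_al)
    basis = basis_matrix(spectrum)

    # calibration phantom: the fixed QA layout, scanned in both domains
    cal_spec = reference_phantom(grid)
    sim_cal, _ = simulate_scan(cal_spec, spectrum, geometry=geometry,
                               flux=config.flux, rng_seed=seed * 1000 + 1)
    real_cal = emulate_real_domain(sim_cal, config.gap, rng_seed=seed * 1000 + 2)
    fits = fit_per_bin(extract_pairs(sim_cal, real_cal, cal_spec))

    def scan(i, domain):
        spec = sample_phantom(seed * 1000 + 10 + i, grid=grid)
        img, lab = simulate_scan(spec, spectrum, geometry=geometry,
                                 flux=config.flux, rng_seed=seed * 1000 + 500 + i)
        if domain == "real":
            img = emulate_real_domain(img, config.gap, rng_seed=seed * 1000 + 800 + i)
        else:
            img = apply_calibration(img, fits)
        return spec, img, lab

    n_p, n_f, n_h = config.n_pretrain, config.n_finetune, config.n_holdout
    pre = [scan(i, "sim") for i in range(n_p)]
    fin = [scan(n_p + i, "real") for i in range(n_f)]
    hold = [scan(n_p + n_f + i, "real") for i in range(n_h)]
    return {
        "grid": grid, "geometry": geometry, "spectrum": spectrum, "basis": basis,
        "cal": (cal_spec, sim_cal, real_cal, fits),
        "pretrain": pre, "finetune": fin, "holdout": hold,
    }


def _train_mdunet(config: ExperimentConfig, data):
    net = build_network(config.network, seed=config.seed)
    tc = replace(config.train, seed=config.seed)
    pre_manifest = DatasetManifest(tuple((img, lab) for _, img, lab in data["pretrain"]), "pretrain")
    fin_manifest = DatasetManifest(tuple((img, lab) for _, img, lab in data["finetune"]), "finetune")
    net, hist_pre = pretrain(net, pre_manifest, tc)
    net, hist_fin = finetune(net, fin_manifest, tc)
    return net, hist_pre + hist_fin


def _train_plain_unet(config: ExperimentConfig, data):
    """Baseline U-net: no weighted skips, cross-entropy-only loss, no transfer."""
    cfg = replace(config.network, weighted_skip_scales=())
    net = build_network(cfg, seed=config.seed + 7)
    loss = LossConfig(gamma=0.0, w_b=1.0, lam=0.0)
    total = config.train.pretrain_epochs + config.train.finetune_epochs
    tc = replace(config.train, seed=config.seed + 7, finetune_epochs=total,
                 freeze_scales_finetune=(), loss=loss)
    fin_manifest = DatasetManifest(tuple((img, lab) for _, img, lab in data["finetune"]), "finetune")
    net, hist = finetune(net, fin_manifest, tc)
    return net, hist


def _decompose_all(config: ExperimentConfig, data, nets):
    """Categorical maps per method on the held-out real-domain scans."""
    out = {m: [] for m in config.methods}
    for _, img, _ in data["holdout"]:
        for method in config.methods:
            if method == "md_ls":
                out[method].append(to_categorical(md_ls(img, data["basis"])))
            elif method == "md_tv":
                out[method].append(to_categorical(md_tv(img, data["basis"], beta=config.tv_beta)))
            else:
                _, lab = predict(nets[method], img)
                out[method].append(lab)
    return out


def run_experiment(config: ExperimentConfig, outdir=None) -> MetricsReport:
    """Execute the six pipeline stages; persist intermediates when outdir given."""
    from . import io as pio

    outdir = Path(outdir) if outdir is not None else None
    stage = "simulate"
    try:
        data = _build_dataset(config)
        if outdir:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "config.yaml").write_text(config.to_yaml())
            (outdir / "provenance.json").write_text(json.dumps(config.fingerprint(), indent=2))
            for i, (spec, img, lab) in enumerate(data["pretrain"][:3]):
                pio.save_image(img, outdir / f"pretrain_{i:03d}.nii")
                pio.save_labels(lab, img.pitch_mm, outdir / f"pretrain_{i:03d}_labels.nii")
        stage = "calibrate"
        fits = data["cal"][3]
        if outdir:
            (outdir / "calibration.json").write_text(
                json.dumps([json.loads(f.to_json()) for f in fits], indent=2))
        nets = {}
        history = {}
        if "md_unet" in config.methods:
            stage = "pretrain/finetune"
            nets["md_unet"], history["md_unet"] = _train_mdunet(config, data)
            if outdir:
                pio.save_checkpoint(nets["md_unet"], outdir / "md_unet.npz")
        if "unet" in config.methods:
            stage = "train-plain-unet"
            nets["unet"], history["unet"] = _train_plain_unet(config, data)
        stage = "decompose"
        maps = _decompose_all(config, data, nets)
        stage = "evaluate"
        gts = [lab for _, _, lab in data["holdout"]]
        rows = {}
        for method, preds in maps.items():
            per_image = [
                evaluate({method: p}, gt).rows[method] for p, gt in zip(preds, gts)
            ]
            rows[method] = {k: float(np.mean([r[k] for r in per_image]))
                            for k in ("miou", "mdsc", "r2")}
        report = MetricsReport(rows=rows, fingerprint=config.fingerprint())
        if outdir:
            (outdir / "report.json").write_text(report.to_json())
            (outdir / "report.csv").write_text(report.to_csv())
            if history:
                lines = ["method,epoch,focal,mge,total"]
                for m, h in history.items():
                    lines += [f"{m},{r['epoch']},{r['focal']},{r['mge']},{r['total']}" for r in h]
                (outdir / "history.csv").write_text("\n".join(lines) + "\n")
        return report
    except Exception as e:
        raise RuntimeError(f"experiment failed at stage '{stage}': {e}") from e


def desk_benchmark(seed: int = 0, config: ExperimentConfig | None = None) -> dict:
    """Seeded desk-scale benchmark: returns held-out mIoU per method."""
    config = replace(config or ExperimentConfig.desk(), seed=seed)
    data = _build_dataset(config)
    nets = {}
    if "md_unet" in config.methods:
        nets["md_unet"], _ = _train_mdunet(config, data)
    if "unet" in config.methods:
        nets["unet"], _ = _train_plain_unet(config, data)
    maps = _decompose_all(config, data, nets)
    gts = [lab for _, _, lab in data["holdout"]]
    return {
        method: float(np.mean([miou(p, gt) for p, gt in zip(preds, gts)]))
        for method, preds in maps.items()
    }


def make_fixtures(seed: int = 0, outdir=None) -> dict:
    """Tiny (64-pixel, 120-view) paired dataset for the unit-test suite.

    Contains at least one phantom per insert-material combination plus the
    fixed QA layout; regeneration with the same seed is bit-identical.
    """
    from . import io as pio

    config = ExperimentConfig.desk(seed=seed, n_pretrain=3, n_finetune=2, n_holdout=1)
    grid = ImageGrid(config.npix, config.fov_mm / config.npix)
    spectrum = build_spectrum(config.kvp, config.hvl_mm_al)
    geometry = Geometry.desk(config.npix, config.n_views)
    from .phantom import InsertSpec

    specs = {
        "reference": reference_phantom(grid),
        "calcium_only": PhantomSpec(inserts=(
            InsertSpec("calcium", 100.0, (-40.0, 0.0), 15.0),
            InsertSpec("calcium", 300.0, (40.0, 0.0), 15.0)), grid=grid),
        "iodine_only": PhantomSpec(inserts=(
            InsertSpec("iodine", 5.0, (0.0, -40.0), 15.0),
            InsertSpec("iodine", 15.0, (0.0, 40.0), 15.0)), grid=grid),
        "mixed": sample_phantom(seed + 2, grid=grid, count_range=(4, 4)),
        "water_only": PhantomSpec(grid=grid),
    }
    out = {}
    for i, (name, spec) in enumerate(specs.items()):
        img, lab = simulate_scan(spec, spectrum, geometry=geometry,
                                 flux=config.flux, rng_seed=seed * 100 + i)
        out[name] = {"spec": spec, "image": img, "labels": lab}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, d in out.items():
            pio.save_image(d["image"], outdir / f"{name}.nii")
            pio.save_labels(d["labels"], d["image"].pitch_mm, outdir / f"{name}_labels.nii")
            (outdir / f"{name}_spec.json").write_text(pio.spec_to_json(d["spec"]))
    return out
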