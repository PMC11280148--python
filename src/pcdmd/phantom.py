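"""Digital multi-energy phantoms with ground-truth material labels.

Phantoms follow the convention of cylindrical water-equivalent QA phantoms
(Gammex-style): a circular water base holding small cylindrical inserts of
calcium or iodine solution at known concentration.  Pixel membership is
decided by the pixel-center point (innermost shape wins), so label maps are
exactly one-hot; partial-volume mixing enters only downstream through the
projection/reconstruction blur.

Coordinates: image arrays are row-major with 0-based indices; the physical
origin (isocenter) sits at pixel index n//2 along each axis — the rotation
center used by the filtered back-projection, so reconstructions and label
maps are co-registered without resampling.  x increases to the right,
y increases downward; pixel (i, j) has center
((j - n//2) * pitch, (i - n//2) * pitch) mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectral import lac

__all__ = [
    "CLASS_NAMES",
    "InsertSpec",
    "ImageGrid",
    "PhantomSpec",
    "ConcentrationSets",
    "rasterize",
    "labels",
    "sample_phantom",
    "augmentation_counts",
]

#: class index convention used everywhere (network output channels included)
CLASS_NAMES = ("background", "water", "calcium", "iodine")
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


class PlacementError(RuntimeError):
    """Rejection sampling could not place the requested inserts."""


@dataclass(frozen=True)
class ImageGrid:
    """Square pixel raster: size in pixels and pitch in mm."""

    npix: int = 256
    pitch_mm: float = 250.0 / 256.0

    @property
    def fov_mm(self) -> float:
        return self.npix * self.pitch_mm

    def centers(self):
        """(x, y) physical coordinates of pixel centers, each (npix, npix)."""
        c = (np.arange(self.npix) - self.npix // 2) * self.pitch_mm
        return np.meshgrid(c, c)  # x varies along columns, y along rows


@dataclass(frozen=True)
class InsertSpec:
    material: str  # "calcium" or "iodine"
    concentration: float  # mg/mL
    center: tuple  # (x, y) mm from isocenter
    radius: float  # mm

    def __post_init__(self):
        if self.material not in ("calcium", "iodine"):
            raise ValueError("insert material must be calcium or iodine")
        if self.radius <= 0:
            raise ValueError("insert radius must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")


@dataclass(frozen=True)
class PhantomSpec:
    base_radius: float = 100.0  # mm
    inserts: tuple = ()
    grid: ImageGrid = field(default_factory=ImageGrid)

    def __post_init__(self):
        object.__setattr__(self, "inserts", tuple(self.inserts))
        if self.base_radius <= 0:
            raise ValueError("base radius must be positive")
        if 2 * self.base_radius > self.grid.fov_mm + 1e-9:
            raise ValueError("phantom base does not fit in the field of view")
        for ins in self.inserts:
            cx, cy = ins.center
            if np.hypot(cx, cy) + ins.radius >= self.base_radius:
                raise ValueError("insert must lie strictly inside the base disk")
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1 :]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise ValueError("inserts must not overlap")


@dataclass(frozen=True)
class ConcentrationSets:
    """Real-phantom and simulated insert concentration sets (mg/mL)."""

    real_ca: tuple = (100.0, 300.0)
    sim_ca: tuple = (100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 900.0, 1000.0)
    real_i: tuple = (2.0, 5.0, 10.0, 15.0)
    sim_i: tuple = (2.0, 4.0, 5.0, 8.0, 10.0, 15.0, 20.0, 25.0, 30.0)

    def __post_init__(self):
        for real, sim in ((self.real_ca, self.sim_ca), (self.real_i, self.sim_i)):
            if not set(real) <= set(sim):
                raise ValueError("real concentration sets must be subsets of simulated sets")
            if any(v <= 0 for v in sim):
                raise ValueError("concentrations must be positive")


def _class_map(spec: PhantomSpec):
    """Per-pixel class index and concentration by pixel-center membership."""
    x, y = spec.grid.centers()
    cls = np.zeros((spec.grid.npix,) * 2, dtype=np.int64)
    conc = np.zeros_like(x)
    inside_base = x**2 + y**2 <= spec.base_radius**2
    cls[inside_base] = CLASS_INDEX["water"]
    for ins in spec.inserts:  # inserts are innermost (pairwise disjoint)
        m = (x - ins.center[0]) ** 2 + (y - ins.center[1]) ** 2 <= ins.radius**2
        cls[m] = CLASS_INDEX[ins.material]
        conc[m] = ins.concentration
    return cls, conc


def labels(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth label map in {0=background, 1=water, 2=calcium, 3=iodine}."""
    return _class_map(spec)[0]


def rasterize(spec: PhantomSpec, energy: float) -> np.ndarray:
    """Monochromatic LAC image (1/cm) at the given energy; background = 0."""
    cls, conc = _class_map(spec)
    img = np.zeros(cls.shape, dtype=float)
    img[cls == CLASS_INDEX["water"]] = lac("water", 0.0, energy)
    for name in ("calcium", "iodine"):
        idx = CLASS_INDEX[name]
        for c in np.unique(conc[cls == idx]):
            img[(cls == idx) & (conc == c)] = lac(name, float(c), energy)
    return img


def concentration_maps(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth continuous maps, shape (3, n, n): water fraction, Ca, I."""
    cls, conc = _class_map(spec)
    out = np.zeros((3,) + cls.shape)
    out[0] = cls >= CLASS_INDEX["water"]  # solutes are additive on the water base
    out[1] = np.where(cls == CLASS_INDEX["calcium"], conc, 0.0)
    out[2] = np.where(cls == CLASS_INDEX["iodine"], conc, 0.0)
    return out


def sample_phantom(
    rng_seed,
    sets: ConcentrationSets | None = None,
    size_range: tuple = (10.0, 25.0),
    count_range: tuple = (2, 6),
    base_radius: float = 100.0,
    grid: ImageGrid | None = None,
    max_tries: int = 2000,
) -> PhantomSpec:
    """Randomized phantom: inserts without overlap, simulated concentration sets.

    ``rng_seed`` may be an int or a ``numpy.random.Generator``; identical
    integer seeds reproduce identical specs bit for bit.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    sets = sets or ConcentrationSets()
    grid = grid or ImageGrid()
    if count_range[1] < count_range[0] or size_range[1] < size_range[0]:
        raise ValueError("ranges must be nonempty")
    n = int(rng.integers(count_range[0], count_range[1] + 1))
    inserts = []
    tries = 0
    while len(inserts) < n:
        tries += 1
        if tries > max_tries:
            raise PlacementError(f"could not place {n} inserts within {max_tries} tries")
        material = "calcium" if rng.random() < 0.5 else "iodine"
        conc = float(rng.choice(sets.sim_ca if material == "calcium" else sets.sim_i))
        radius = float(rng.uniform(*size_range))
        r_max = base_radius - radius - 1.0
        if r_max <= 0:
            continue
        rho = r_max * np.sqrt(rng.random())
        phi = rng.uniform(0, 2 * np.pi)
        center = (rho * np.cos(phi), rho * np.sin(phi))
        ok = all(
            np.hypot(center[0] - o.center[0], center[1] - o.center[1]) >= radius + o.radius + 1.0
            for o in inserts
        )
        if ok:
            inserts.append(InsertSpec(material, conc, center, radius))
    return PhantomSpec(base_radius=base_radius, inserts=tuple(inserts), grid=grid)


def reference_phantom(grid: ImageGrid | None = None, base_radius: float = 100.0) -> PhantomSpec:
    """Fixed layout mirroring the real QA phantom: 2 Ca + 4 I inserts (15 mm radius)."""
    grid = grid or ImageGrid()
    sets = ConcentrationSets()
    concs = [("calcium", c) for c in sets.real_ca] + [("iodine", c) for c in sets.real_i]
    r_ring = 0.55 * base_radius
    inserts = []
    for k, (mat, c) in enumerate(concs):
        phi = 2 * np.pi * k / len(concs)
        inserts.append(InsertSpec(mat, c, (r_ring * np.cos(phi), r_ring * np.sin(phi)), 15.0))
    return PhantomSpec(base_radius=base_radius, inserts=tuple(inserts), grid=grid)


def augmentation_counts(sets: ConcentrationSets | None = None) -> tuple:
    """Number of extra simulated concentrations beyond the real phantom sets."""
    sets = sets or ConcentrationSets()
    return (
        len(set(sets.sim_ca) - set(sets.real_ca)),
        len(set(sets.sim_i) - set(sets.real_i)),
    )
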