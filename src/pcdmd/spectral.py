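"""X-ray spectrum, attenuation tables and per-bin effective LACs.

This module carries the energy physics of the workbench:

* a filtered Kramers bremsstrahlung spectrum model whose aluminum filtration
  is solved so that the beam's half-value layer (HVL) matches a measured
  target,
* tabulated mass-attenuation coefficients for water, calcium, iodine and
  aluminum with log-log interpolation and absorption-edge-aware branching,
* fluence-weighted effective linear attenuation coefficients (LAC, 1/cm) per
  energy bin, and the bins x materials basis matrix used by the analytic
  decomposition baselines.

Solutes (calcium, iodine) follow the dilute additive-mixture rule: an aqueous
solution at concentration c mg/mL attenuates like water plus c/1000 g/cm^3 of
the pure solute; water displacement is neglected.  All energies are in keV,
lengths in cm unless stated otherwise.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EnergyGrid",
    "Spectrum",
    "MaterialTable",
    "EnergyBinSet",
    "BasisMatrix",
    "DEFAULT_BINS",
    "DENSITY_G_CM3",
    "IODINE_K_EDGE_KEV",
    "load_material_table",
    "build_spectrum",
    "measure_hvl",
    "mean_energy",
    "lac",
    "effective_bin_lac",
    "basis_matrix",
]

#: densities of the pure materials, g/cm^3
DENSITY_G_CM3 = {"water": 1.0, "calcium": 1.55, "iodine": 4.93, "aluminum": 2.699}

#: iodine K-shell binding energy, keV
IODINE_K_EDGE_KEV = 33.2

_SOLUTES = ("calcium", "iodine")


class UnreachableHVLError(ValueError):
    """No aluminum filter thickness in range achieves the requested HVL."""


class EmptyBinError(ValueError):
    """An energy bin contains no spectrum fluence."""


@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing photon-energy samples in keV, bounded to [1, 140]."""

    energies: np.ndarray
    step: float

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "energies", e)
        if e.ndim != 1 or e.size < 2:
            raise ValueError("energy grid needs at least two samples")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if e[0] < 1.0 or e[-1] > 140.0:
            raise ValueError("energy grid must lie within [1, 140] keV")
        if self.step <= 0:
            raise ValueError("grid step must be positive")

    @classmethod
    def default(cls, e_min: float = 1.0, e_max: float = 140.0, step: float = 1.0):
        return cls(np.arange(e_min, e_max + 0.5 * step, step), step)


@dataclass(frozen=True)
class Spectrum:
    """Sampled photon fluence per energy, with its tube voltage and HVL."""

    grid: EnergyGrid
    fluence: np.ndarray
    kvp: float
    hvl_mm_al: float

    def __post_init__(self):
        f = np.asarray(self.fluence, dtype=float)
        object.__setattr__(self, "fluence", f)
        if f.shape != self.grid.energies.shape:
            raise ValueError("fluence and grid shapes differ")
        if np.any(f < 0):
            raise ValueError("fluence must be nonnegative")
        if np.any(f[self.grid.energies > self.kvp] > 0):
            raise ValueError("fluence above kvp must be zero")
        if f.sum() <= 0:
            raise ValueError("total fluence must be positive")


@dataclass(frozen=True)
class MaterialTable:
    """Mass-attenuation samples (cm^2/g) with edge-aware branch boundaries."""

    material: str
    energies: np.ndarray
    mass_atten: np.ndarray
    density: float
    #: start indices of interpolation branches (edges split branches)
    branch_starts: tuple = field(default=(0,))

    def __call__(self, energy) -> np.ndarray:
        """Log-log interpolated mass attenuation, never across an edge."""
        e = np.atleast_1d(np.asarray(energy, dtype=float))
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise ValueError(
                f"energy outside {self.material} table range "
                f"[{self.energies[0]}, {self.energies[-1]}] keV"
            )
        out = np.empty_like(e)
        starts = list(self.branch_starts) + [len(self.energies)]
        for b in range(len(self.branch_starts)):
            lo, hi = starts[b], starts[b + 1]
            e_lo = self.energies[lo]
            e_hi = self.energies[hi - 1]
            if b == 0:
                mask = e <= e_hi
            elif b == len(self.branch_starts) - 1:
                mask = e >= e_lo
            else:
                mask = (e >= e_lo) & (e <= e_hi)
            if not np.any(mask):
                continue
            out[mask] = np.exp(
                np.interp(
                    np.log(e[mask]),
                    np.log(self.energies[lo:hi]),
                    np.log(self.mass_atten[lo:hi]),
                )
            )
        return out if np.ndim(energy) else float(out[0])


_TABLE_CACHE: dict[str, MaterialTable] = {}


def load_material_table(material: str) -> MaterialTable:
    """Load a packaged mass-attenuation table (cached)."""
    if material in _TABLE_CACHE:
        return _TABLE_CACHE[material]
    if material not in DENSITY_G_CM3:
        raise ValueError(f"unknown material {material!r}")
    text = resources.files("pcdmd.data").joinpath(f"{material}.csv").read_text()
    rows = [
        r
        for r in csv.reader(text.splitlines())
        if r and not r[0].startswith("#") and r[0] != "energy_keV"
    ]
    e = np.array([float(r[0]) for r in rows])
    mu = np.array([float(r[1]) for r in rows])
    if np.any(mu <= 0):
        raise ValueError("mass attenuation must be positive")
    # adjacent rows closer than 0.1% in energy mark an absorption edge
    edges = np.nonzero(np.diff(e) < 1e-3 * e[:-1])[0]
    branch_starts = (0, *(int(i) + 1 for i in edges))
    table = MaterialTable(material, e, mu, DENSITY_G_CM3[material], branch_starts)
    _TABLE_CACHE[material] = table
    return table


@dataclass(frozen=True)
class EnergyBinSet:
    """Ordered, contiguous, non-overlapping energy bins [low, high) in keV.

    The final bin is closed at its upper limit so the full band is tiled.
    """

    bins: tuple

    def __post_init__(self):
        bins = tuple((float(lo), float(hi)) for lo, hi in self.bins)
        object.__setattr__(self, "bins", bins)
        for lo, hi in bins:
            if hi <= lo:
                raise ValueError("bin high must exceed low")
        for (_, hi), (lo2, _) in zip(bins[:-1], bins[1:]):
            if lo2 != hi:
                raise ValueError("bins must be contiguous and non-overlapping")

    def __len__(self):
        return len(self.bins)

    def mask(self, energies: np.ndarray, index: int) -> np.ndarray:
        lo, hi = self.bins[index]
        m = (energies >= lo) & (energies < hi)
        if index == len(self.bins) - 1:
            m |= energies == hi
        return m

    @classmethod
    def default(cls) -> "EnergyBinSet":
        """The three acquisition bins: 30-50, 50-65 and 65-140 keV."""
        return cls(((30.0, 50.0), (50.0, 65.0), (65.0, 140.0)))


DEFAULT_BINS = EnergyBinSet.default()


@dataclass(frozen=True)
class BasisMatrix:
    """Per-bin effective LAC per unit concentration, bins x materials.

    Water is an absolute LAC column (1/cm at unit volume fraction); solute
    columns are sensitivities in 1/cm per mg/mL.
    """

    values: np.ndarray
    bin_set: EnergyBinSet
    materials: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "materials", tuple(self.materials))
        if v.shape != (len(self.bin_set), len(self.materials)):
            raise ValueError("basis shape does not match bins/materials")
        if np.any(v < 0):
            raise ValueError("basis entries must be nonnegative")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values))


# ---------------------------------------------------------------------------
# spectrum model


def _al_mu_linear(energies: np.ndarray) -> np.ndarray:
    t = load_material_table("aluminum")
    return t(energies) * t.density  # 1/cm


def measure_hvl(spectrum: Spectrum, x_max_mm: float = 300.0) -> float:
    """Aluminum thickness (mm) halving the total detected fluence."""
    mu = _al_mu_linear(spectrum.grid.energies)
    total = spectrum.fluence.sum()

    def trans(x_mm):
        return spectrum.fluence @ np.exp(-mu * x_mm / 10.0) / total - 0.5

    return float(brentq(trans, 0.0, x_max_mm, xtol=1e-12, rtol=1e-14))


def mean_energy(spectrum: Spectrum) -> float:
    return float(spectrum.grid.energies @ spectrum.fluence / spectrum.fluence.sum())


def build_spectrum(kvp: float, hvl_target: float, grid: EnergyGrid | None = None) -> Spectrum:
    """Kramers bremsstrahlung hardened by HVL-matched aluminum filtration.

    The unfiltered fluence is proportional to E*(kvp - E) for E <= kvp.  An
    aluminum filter thickness is solved by bisection so that a further
    ``hvl_target`` mm of aluminum halves the total fluence (relative
    tolerance 1e-6).
    """
    if not 40.0 <= kvp <= 140.0:
        raise ValueError("kvp must be within [40, 140] kV")
    if hvl_target <= 0:
        raise ValueError("hvl_target must be positive")
    if grid is None:
        grid = EnergyGrid.default(e_max=kvp)
    e = grid.energies
    if e[0] > 1.0 or e[-1] < kvp:
        raise ValueError("grid must span [1, kvp]")
    s0 = np.clip(e * (kvp - e), 0.0, None)
    s0[e > kvp] = 0.0
    mu = _al_mu_linear(e)

    def hvl_of(t_mm):
        f = s0 * np.exp(-mu * t_mm / 10.0)
        sp = Spectrum(grid, f, kvp, hvl_target)
        return measure_hvl(sp)

    lo, hi = 0.0, 100.0
    if hvl_of(lo) > hvl_target * (1 + 1e-9) or hvl_of(hi) < hvl_target:
        raise UnreachableHVLError(
            f"no Al filter in [0, 100] mm reaches HVL {hvl_target} mm at {kvp} kV"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        h = hvl_of(mid)
        if abs(h - hvl_target) <= 1e-8 * hvl_target:
            lo = hi = mid
            break
        if h < hvl_target:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    return Spectrum(grid, s0 * np.exp(-mu * t / 10.0), kvp, hvl_target)


# ---------------------------------------------------------------------------
# LAC model


def lac(material: str, concentration: float, energy) -> np.ndarray | float:
    """Linear attenuation coefficient in 1/cm.

    Solutes use the dilute additive-mixture rule
    ``mu_water(E) + mass_atten_solute(E) * concentration / 1000``; water and
    aluminum are pure materials at their nominal density (concentration is
    ignored for them).
    """
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    if material in ("water", "aluminum"):
        t = load_material_table(material)
        return t(energy) * t.density
    if material not in _SOLUTES:
        raise ValueError(f"unknown material {material!r}")
    tw = load_material_table("water")
    ts = load_material_table(material)
    return tw(energy) * tw.density + ts(energy) * (concentration / 1000.0)


def effective_bin_lac(
    spectrum: Spectrum,
    bin_interval: tuple | int,
    material: str,
    concentration: float,
    bin_set: EnergyBinSet | None = None,
) -> float:
    """Fluence-weighted mean LAC over a bin, weights renormalized in-bin."""
    e = spectrum.grid.energies
    if isinstance(bin_interval, int):
        if bin_set is None:
            bin_set = DEFAULT_BINS
        m = bin_set.mask(e, bin_interval)
    else:
        lo, hi = bin_interval
        m = (e >= lo) & (e <= hi)
    w = spectrum.fluence[m]
    if w.sum() <= 0:
        raise EmptyBinError("no fluence inside the requested bin")
    return float(w @ np.atleast_1d(lac(material, concentration, e[m])) / w.sum())


def basis_matrix(
    spectrum: Spectrum,
    bin_set: EnergyBinSet = DEFAULT_BINS,
    materials: Sequence[str] = ("water", "calcium", "iodine"),
) -> BasisMatrix:
    """Linearized per-bin basis: water absolute, solutes per mg/mL."""
    e = spectrum.grid.energies
    cols = []
    for mat in materials:
        col = []
        for b in range(len(bin_set)):
            m = bin_set.mask(e, b)
            w = spectrum.fluence[m]
            if w.sum() <= 0:
                raise EmptyBinError(f"no fluence inside bin {b}")
            if mat == "water":
                t = load_material_table("water")
                vals = t(e[m]) * t.density
            else:
                vals = load_material_table(mat)(e[m]) / 1000.0
            col.append(float(w @ vals / w.sum()))
        cols.append(col)
    values = np.array(cols).T
    bm = BasisMatrix(values, bin_set, tuple(materials))
    if values.shape[0] >= values.shape[1]:
        if not np.isfinite(bm.condition_number) or bm.condition_number > 1e10:
            warnings.warn(
                f"basis matrix is ill-conditioned (cond={bm.condition_number:.3g})",
                RuntimeWarning,
                stacklevel=2,
            )
    return bm
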