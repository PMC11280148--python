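"""Classical image-domain basis material decomposition baselines.

MD-LS solves, independently per pixel, min_x ||B x - l||^2 where l is the
pixel's 3-bin LAC vector and B the linearized bins x materials basis matrix;
negative components are clamped to zero (with a recorded mask).  MD-TV
minimizes the same data term plus beta * sum_m TV(x_m) (isotropic total
variation per material map) by proximal gradient with fixed step 1/L, the TV
proximal operator being evaluated by Chambolle's algorithm.  An
accept-if-decrease safeguard keeps the objective monotone non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.restoration import denoise_tv_chambolle

from .phantom import CLASS_INDEX
from .simulator import MultiBinImage
from .spectral import BasisMatrix

__all__ = ["ConcentrationMaps", "md_ls", "md_tv", "to_categorical", "tv_norm"]


@dataclass(frozen=True)
class ConcentrationMaps:
    """Per-material maps: water volume fraction, then solute mg/mL maps."""

    maps: np.ndarray  # (n_materials, H, W)
    materials: tuple
    pitch_mm: float
    clamped: np.ndarray | None = None  # mask where negatives were clamped
    converged: bool = True
    objective: float | None = None
    objective_trace: tuple = ()

    def __post_init__(self):
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("concentration maps must be finite")


def _check_basis(basis: BasisMatrix):
    B = basis.values
    if B.shape[0] < B.shape[1]:
        raise ValueError("need at least as many bins as materials")
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"singular or near-singular basis (cond={cond:.3g})")
    return B, cond


def md_ls(image: MultiBinImage, basis: BasisMatrix) -> ConcentrationMaps:
    """Per-pixel least squares via the pseudoinverse; negatives clamped to 0."""
    B, _ = _check_basis(basis)
    l = image.data.reshape(B.shape[0], -1)  # (bins, npix)
    x = np.linalg.pinv(B) @ l  # (materials, npix)
    maps = x.reshape((B.shape[1],) + image.data.shape[1:])
    clamped = maps < 0
    maps = np.where(clamped, 0.0, maps)
    return ConcentrationMaps(maps, basis.materials, image.pitch_mm, clamped=clamped)


def tv_norm(m: np.ndarray) -> float:
    """Isotropic total variation of a 2D map (forward differences)."""
    gx = np.diff(m, axis=1, append=m[:, -1:])
    gy = np.diff(m, axis=0, append=m[-1:, :])
    return float(np.sqrt(gx**2 + gy**2).sum())


def _objective(B, x, l, beta):
    resid = np.einsum("bm,mij->bij", B, x) - l
    obj = 0.5 * float((resid**2).sum())
    if beta > 0:
        obj += beta * sum(tv_norm(x[m]) for m in range(x.shape[0]))
    return obj


def md_tv(
    image: MultiBinImage,
    basis: BasisMatrix,
    beta: float = 0.05,
    iters: int = 100,
    tol: float = 1e-6,
) -> ConcentrationMaps:
    """TV-regularized decomposition by proximal gradient (step 1/L).

    L is the squared spectral norm of the basis; at beta = 0 the iteration
    is initialized at, and stays on, the per-pixel least-squares solution.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    B, _ = _check_basis(basis)
    l = image.data
    # initialize at the unclamped per-pixel LS solution (stationary at beta=0)
    x = (np.linalg.pinv(B) @ image.data.reshape(B.shape[0], -1)).reshape(
        (B.shape[1],) + image.data.shape[1:]
    )
    L = np.linalg.norm(B, 2) ** 2
    step = 1.0 / L
    obj = _objective(B, x, l, beta)
    trace = [obj]
    converged = False
    for _ in range(iters):
        grad = np.einsum("mb,bij->mij", B.T, np.einsum("bm,mij->bij", B, x) - l)
        z = x - step * grad
        if beta > 0:
            z = np.stack(
                [denoise_tv_chambolle(z[m], weight=beta * step, eps=1e-5, max_num_iter=200)
                 for m in range(z.shape[0])]
            )
        new_obj = _objective(B, z, l, beta)
        if new_obj > obj:  # safeguard: never accept an objective increase
            converged = True
            break
        trace.append(new_obj)
        if obj - new_obj < tol * max(abs(obj), 1.0):
            x, obj = z, new_obj
            converged = True
            break
        x, obj = z, new_obj
    else:
        warnings.warn(
            f"MD-TV did not converge in {iters} iterations (objective {obj:.4g})",
            RuntimeWarning,
            stacklevel=2,
        )
    clamped = x < 0
    x = np.where(clamped, 0.0, x)
    return ConcentrationMaps(
        x, basis.materials, image.pitch_mm, clamped=clamped, converged=converged,
        objective=obj, objective_trace=tuple(trace),
    )


def to_categorical(
    maps: ConcentrationMaps,
    thresholds: dict | None = None,
    reference: dict | None = None,
) -> np.ndarray:
    """Concentration maps -> label map scorable against ground truth.

    Under the additive solute model the water fraction stays near 1 inside
    inserts, so solutes take precedence: a pixel is background when every map
    is below its threshold, water when only the water map clears its
    threshold, and otherwise the argmax over solute maps normalized by their
    reference concentrations (ties to the lower class index).  The default
    iodine threshold sits above the spurious iodine that beam hardening
    induces in water regions of a full-size phantom.
    """
    thresholds = thresholds or {"water": 0.25, "calcium": 30.0, "iodine": 3.0}
    reference = reference or {"water": 1.0, "calcium": 300.0, "iodine": 15.0}
    for mat, ref in reference.items():
        if ref <= 0:
            raise ValueError("reference concentrations must be positive")
    solutes = [m for m in maps.materials if m != "water"]
    by_name = {m: maps.maps[k] for k, m in enumerate(maps.materials)}
    label = np.zeros(maps.maps.shape[1:], dtype=np.int64)
    if "water" in by_name:
        label[by_name["water"] >= thresholds["water"]] = CLASS_INDEX["water"]
    if solutes:
        above = np.stack([by_name[m] >= thresholds[m] for m in solutes])
        scores = np.stack([by_name[m] / reference[m] for m in solutes])
        any_solute = above.any(axis=0)
        scores = np.where(above, scores, -np.inf)
        winner = scores.argmax(axis=0)
        for k, mat in enumerate(solutes):
            label[any_solute & (winner == k)] = CLASS_INDEX[mat]
    return label
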