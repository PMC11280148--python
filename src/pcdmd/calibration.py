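"""Sim-to-real LAC calibration via concentration-correlation curve fitting.

ROI means of matching inserts in a simulated and a real(-emulated) scan form
(lac_sim, lac_real) pairs; a nonlinear least-squares fit of

    lac_real = a * exp(-b * lac_sim) + c            (exp3, default)

or of a 4-parameter logistic

    lac_real = a / (1 + exp(-b * (lac_sim - d))) + c    (logistic4)

maps simulated pixel values into the real domain.  Fits are performed per
energy bin (LAC scales differ strongly across bins); calibrated simulation
images are then used for network pre-training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import least_squares

from .phantom import PhantomSpec
from .simulator import MultiBinImage

__all__ = [
    "CalibrationPair",
    "CalibrationFit",
    "extract_pairs",
    "fit_lac_curve",
    "fit_per_bin",
    "apply_calibration",
]


class FitFailureError(RuntimeError):
    def __init__(self, msg, best_residual=np.inf):
        super().__init__(msg)
        self.best_residual = best_residual


@dataclass(frozen=True)
class CalibrationPair:
    concentration: float  # mg/mL
    lac_sim: float  # 1/cm
    lac_real: float  # 1/cm
    material: str
    bin_index: int

    def __post_init__(self):
        if not (np.isfinite(self.lac_sim) and np.isfinite(self.lac_real)):
            raise ValueError("LAC values must be finite")


@dataclass(frozen=True)
class CalibrationFit:
    a: float
    b: float
    c: float
    d: float | None = None
    residual_rms: float = 0.0
    variant: str = "exp3"
    bin_index: int | None = None

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.variant == "exp3":
            return self.a * np.exp(-self.b * x) + self.c
        return self.a / (1.0 + np.exp(-self.b * (x - self.d))) + self.c

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "CalibrationFit":
        return cls(**json.loads(text))


def _roi_mean(img2d: np.ndarray, pitch_mm: float, center, radius_mm: float) -> float:
    n = img2d.shape[0]
    c = (np.arange(n) - n // 2) * pitch_mm
    xx, yy = np.meshgrid(c, c)
    m = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius_mm**2
    if not np.any(m):
        raise ValueError("ROI radius below one pixel")
    return float(img2d[m].mean())


def extract_pairs(
    sim: MultiBinImage,
    real: MultiBinImage,
    spec: PhantomSpec,
    roi_radius: float | None = None,
) -> list:
    """One (lac_sim, lac_real) pair per insert per bin, from disk-ROI means."""
    if sim.data.shape != real.data.shape:
        raise ValueError("images must share the grid")
    pairs = []
    for ins in spec.inserts:
        r = roi_radius if roi_radius is not None else 0.5 * ins.radius
        if r > 0.8 * ins.radius:
            warnings.warn(
                f"ROI radius {r} mm close to insert boundary; shrinking to {0.8 * ins.radius:.2f} mm",
                RuntimeWarning,
                stacklevel=2,
            )
            r = 0.8 * ins.radius
        if r < sim.pitch_mm:
            raise ValueError("ROI radius below one pixel")
        for b in range(sim.data.shape[0]):
            pairs.append(
                CalibrationPair(
                    concentration=ins.concentration,
                    lac_sim=_roi_mean(sim.data[b], sim.pitch_mm, ins.center, r),
                    lac_real=_roi_mean(real.data[b], real.pitch_mm, ins.center, r),
                    material=ins.material,
                    bin_index=b,
                )
            )
    return pairs


def _exp3_linear_solve(x, y, b):
    """Given b, (a, c) minimizing ||a*exp(-b*x) + c - y|| in closed form."""
    e = np.exp(-b * x)
    A = np.stack([e, np.ones_like(e)], axis=1)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[0], coef[1]


def fit_lac_curve(pairs, variant: str = "exp3") -> CalibrationFit:
    """Multi-start iterative nonlinear least squares for the LAC curve.

    Starts b at {0.1, 1, 10} (with both signs of the profile handled by the
    closed-form (a, c) solve), keeps the best residual; convergence at
    gradient norm 1e-10 or 500 iterations.
    """
    n_par = 3 if variant == "exp3" else 4
    if len(pairs) < n_par:
        raise ValueError(f"need at least {n_par} pairs")
    x = np.array([p.lac_sim for p in pairs], dtype=float)
    y = np.array([p.lac_real for p in pairs], dtype=float)
    bins = {p.bin_index for p in pairs}
    bin_index = bins.pop() if len(bins) == 1 else None
    if np.ptp(x) == 0:
        raise ValueError("degenerate pairs: lac_sim values all identical")

    best = None
    if variant == "exp3":

        def resid(theta):
            a, b, c = theta
            return a * np.exp(-b * x) + c - y

        for b0 in (0.1, 1.0, 10.0):
            a0, c0 = _exp3_linear_solve(x, y, b0)
            try:
                sol = least_squares(
                    resid, [a0, b0, c0], gtol=1e-10, xtol=1e-14, ftol=1e-14, max_nfev=500 * 3
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitFailureError("all exp3 starts failed")
        a, b, c = best.x
        d = None
    elif variant == "logistic4":

        def resid(theta):
            a, b, c, d = theta
            return a / (1.0 + np.exp(-b * (x - d))) + c - y

        span = np.ptp(y) if np.ptp(y) > 0 else 1.0
        for b0 in (0.1, 1.0, 10.0):
            for sign in (1.0, -1.0):
                start = [sign * 2 * span, b0, y.min() if sign > 0 else y.max(), float(np.median(x))]
                try:
                    sol = least_squares(resid, start, gtol=1e-10, xtol=1e-14, ftol=1e-14, max_nfev=2000)
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is None:
            raise FitFailureError("all logistic4 starts failed")
        a, b, c, d = best.x
    else:
        raise ValueError("variant must be 'exp3' or 'logistic4'")

    res = resid(best.x)
    rms = float(np.sqrt(np.mean(res**2)))
    # sanity: never worse than the nested constant model
    const_rms = float(np.sqrt(np.mean((y - y.mean()) ** 2)))
    if rms > const_rms * (1 + 1e-9):
        a, b, c, d = (0.0, 1.0, float(y.mean()), None if variant == "exp3" else float(np.median(x)))
        rms = const_rms
    return CalibrationFit(
        a=float(a), b=float(b), c=float(c), d=None if d is None else float(d),
        residual_rms=rms, variant=variant, bin_index=bin_index,
    )


def fit_per_bin(pairs, variant: str = "exp3") -> list:
    """Independent fit for each energy bin present in the pairs."""
    bins = sorted({p.bin_index for p in pairs})
    return [fit_lac_curve([p for p in pairs if p.bin_index == b], variant) for b in bins]


def apply_calibration(image: MultiBinImage, fit) -> MultiBinImage:
    """Pointwise application of one fit (all bins) or a per-bin list of fits.

    Pixel values are mapped into the real-domain LAC range; the provenance
    tag stays ``simulated`` (calibrated simulations are the pre-training set,
    emulator output the fine-tuning set).
    """
    from dataclasses import replace

    fits = list(fit) if isinstance(fit, (list, tuple)) else [fit] * image.data.shape[0]
    if len(fits) != image.data.shape[0]:
        raise ValueError("need one fit per bin")
    out = np.stack([f(image.data[b]) for b, f in enumerate(fits)])
    return replace(image, data=out)
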