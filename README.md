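# pcdmd — material decomposition workbench for three-bin photon-counting CT

Photon-counting detectors record the energy of individual X-ray photons, so a
single CT scan yields co-registered images in several energy windows.  From
three such windows (30–50, 50–65 and 65–140 keV) the material at each pixel —
water, calcium or iodine contrast agent — can be recovered, which is the basis
of low-dose contrast imaging and calcium/iodine separation in the head.

`pcdmd` is a self-contained workbench for studying this decomposition when no
scanner data are available.  It

* simulates three-bin scans of digital water phantoms with calcium/iodine
  inserts (filtered Kramers spectrum matched to a measured half-value layer,
  exact polychromatic disk projections, Poisson noise, filtered
  back-projection),
* manufactures a "real" domain with a configurable sim-to-real gap, and fits
  the concentration-correlation calibration
  `LAC_real = a·exp(−b·LAC_sim) + c` per energy bin that maps simulated
  images into it,
* trains **MD-Unet** — a 3D U-net over the bin-stacked volume with weighted
  skip connections and a customized loss `FL + λ·MGE` (background-weighted
  focal loss, γ = 2, plus a Sobel mean-gradient-error term, λ = 0.01) — by
  pre-training on calibrated simulations and fine-tuning on real-domain scans
  with the first encoder scale frozen,
* decomposes with classical baselines (per-pixel least squares **MD-LS** and
  TV-regularized **MD-TV**), and
* scores everything against exact ground truth with CNR, mean IoU, mean Dice
  and R².

The network runs on a small numpy reverse-mode autodiff engine shipped with
the package (`pcdmd.nn`); there is no GPU or deep-learning-framework
dependency.  See `docs/methods.md` for the full model description.

## Worked example

Simulate the QA phantom (two calcium inserts at 100/300 mg/mL, four iodine
inserts at 2–15 mg/mL), emulate its real-domain scan, fit the per-bin
calibration curves, and decompose with least squares:

```python
import numpy as np
from pcdmd.spectral import build_spectrum, basis_matrix
from pcdmd.phantom import ImageGrid, reference_phantom
from pcdmd.simulator import Geometry, simulate_scan, emulate_real_domain
from pcdmd.calibration import extract_pairs, fit_per_bin
from pcdmd.baselines import md_ls, to_categorical
from pcdmd.metrics import miou

spectrum = build_spectrum(kvp=140.0, hvl_target=10.0)
phantom = reference_phantom(ImageGrid(128, 250.0 / 128))
image, labels = simulate_scan(phantom, spectrum,
                              geometry=Geometry.desk(128, 120), flux=np.inf)
real = emulate_real_domain(image, rng_seed=0)

fits = fit_per_bin(extract_pairs(image, real, phantom))
print([round(f.residual_rms, 5) for f in fits])
# [0.00078, 0.00105, 0.00074]

pred = to_categorical(md_ls(image, basis_matrix(spectrum)))
print(round(miou(pred, labels), 3))
# 0.589
```

The calibration residuals (RMS per bin, 1/cm) are small compared with water's
~0.2–0.28 1/cm bin LACs: the three-parameter exponential captures the
emulated sim-to-real gap.  The least-squares mIoU of 0.589 illustrates the
baseline's known weakness — beam hardening of dense calcium is misread as
iodine — which the learned decomposition is designed to overcome; the full
comparison is produced by the experiment driver:

```sh
pcdmd run-all --preset desk --seed 1 --out runs/desk
```

which simulates the datasets, calibrates, pre-trains and fine-tunes MD-Unet,
trains a plain U-net (cross-entropy only, no transfer) for reference, runs
MD-LS and MD-TV, and writes `report.json`/`report.csv` with mIoU, mDSC and R²
per method, plus training history and a provenance record.  The same
operations are available as `pcdmd simulate / calibrate / train / decompose /
evaluate / make-fixtures`.

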