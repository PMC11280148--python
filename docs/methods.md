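# Methods

## Problem setting

Photon-counting CT acquires projection data in several photon-energy windows
in a single scan.  This workbench studies image-domain **basis material
decomposition** of three-bin acquisitions (bin 1: 30–50 keV, bin 2:
50–65 keV, bin 3: 65–140 keV) into per-pixel classes
{background, water, calcium, iodine}, comparing a 3D U-net trained with a
customized loss and a simulation-to-real transfer protocol (**MD-Unet**)
against per-pixel least squares (**MD-LS**) and total-variation-regularized
least squares (**MD-TV**).

Because no spectral scanner data are packaged, the workbench is closed-loop:
it simulates its own multi-energy scans from digital phantoms, manufactures a
"real" domain with a configurable sim-to-real gap, and evaluates every method
against exact ground-truth labels.

## Spectrum and attenuation model

The tube spectrum is filtered Kramers bremsstrahlung: photon fluence
proportional to `E (kVp − E)` for `E ≤ kVp` on a 1 keV grid over
[1, 140] keV, hardened by an aluminum filter whose thickness is solved by
bisection so that one further half-value layer (HVL) of aluminum halves the
total fluence (relative tolerance 1e-6).  The default beam is 140 kV with a
10 mm Al HVL.  Under this fluence form the unfiltered 140 kV beam already has
an HVL of 8.1 mm Al, so HVL targets below that are rejected as unreachable;
10 mm corresponds to roughly 2.5 mm Al of added filtration.

Mass-attenuation tables for water, calcium, iodine and aluminum ship as
package CSVs compiled from standard published anchor values plus a calibrated
photoelectric + Compton parameterization for rows without a remembered
anchor; the diagnostic band (15–140 keV) tracks published values closely
while the sub-10 keV region is approximate (L/M edge structure omitted).
Interpolation is log–log and never crosses an absorption edge (edges are
encoded as duplicate-energy row pairs; iodine's K edge at 33.2 keV).

Aqueous solutes follow the dilute additive-mixture rule: a solution at
`c` mg/mL attenuates like water plus `c/1000` g/cm³ of pure solute, with
water displacement neglected.  Effective per-bin LACs are fluence-weighted
in-bin means; the bins × materials **basis matrix** holds the water LAC
column (1/cm) and solute sensitivity columns (1/cm per mg/mL) and has
condition number ≈ 3·10³ for the default spectrum.

## Phantoms and ground truth

Phantoms are water disks (default radius 100 mm in a 250 mm field of view)
with non-overlapping cylindrical inserts of calcium (100–1000 mg/mL) or
iodine (2–30 mg/mL), the concentration sets of the multi-energy QA phantom
plus the simulated augmentation sets.  Randomized phantoms draw 2–6 inserts
with radii uniform in 10–25 mm — bracketing the physical 15 mm insert radius
of the real QA phantom — and positions uniform in the base disk, by
rejection sampling.  Pixel membership is decided by the pixel-center point,
so label maps are strictly one-hot; partial volume appears only through the
projection/reconstruction blur, as in real scans.

Coordinates: the physical origin is pixel index `n//2` on both axes — the
rotation center of the back-projection — so reconstructions and labels are
co-registered without resampling.

## Scan simulation

Forward projection evaluates exact chord lengths of every ray through every
disk (no rasterization error) and applies the polychromatic Beer–Lambert law
per energy sample; counts are summed within each bin, Poisson noise is drawn
when the open-beam count (`flux`, per detector element over the full band) is
finite, zero-count rays are clamped to one count (logged), and the data are
log-transformed against the in-bin open-beam counts.  Reconstruction is
standard parallel-beam FBP (frequency-domain ramp, optional Hann
apodization — the default for noisy data) with linear back-projection; the
prototype's fan geometry (source–isocenter 227.5 mm, 1440 views, 48 detector
modules tiling 3840 row pixels) is available and reconstructed by rebinning
to parallel rays.

Desk-scale default: 64² images, 120 views, 250 mm FOV, `flux` = 4·10⁵.  The
flux is quoted per detector element, so it scales with the element width:
4·10⁵ counts on a 3.9 mm element corresponds to 10⁵ on the ~1 mm elements of
a 256² acquisition.

## The real-domain emulator and LAC calibration

Prototype scans are not available, so a **real-domain emulator** manufactures
the target domain: a pointwise monotone nonlinearity
`real = a* exp(−b* sim) + c*` with defaults (−1.4, 0.8, 1.4) — identity-like
at small LAC, mildly compressive above, exact at zero since `a* + c* = 0` —
followed by additive Gaussian noise (σ = 0.01 cm⁻¹) and an optional
radius-dependent sinusoidal ring gain (off by default).

Calibration mirrors the concentration-correlation procedure: insert-ROI means
from a simulated and a real-domain scan of the same QA layout form
(lac_sim, lac_real) pairs; a multi-start iterative nonlinear least-squares
fit of the 3-parameter exponential `a·exp(−b·x) + c` (a 4-parameter logistic
variant is also provided) is performed **per bin**, because LAC scales differ
strongly across bins.  The fitted curves are applied pixelwise to simulation
images before pre-training.  On noiseless pointwise pairs the fit recovers
the generating parameters to better than 1e-6; on ROI-mean pairs recovery is
limited (~1e-4) by the intra-ROI texture passed through the nonlinearity.

## MD-Unet

The three bin images are stacked into a (1 channel, 3 bins, H, W) volume.
The network is a five-scale 3D encoder–decoder: two 3×3×3 convolutions per
scale (each followed by batch normalization and ReLU), spatial-only 1×2×2
max-pooling between encoder scales, spatial 1×2×2 up-convolutions in the
decoder, and skip connections at every scale — gated by learnable scalars
(initialized at 1) on scales 1 and 2, plain concatenation elsewhere.
Channels double per scale from 64 to 1024 at the deepest scale.  Pooling
never touches the bin axis, so the bin depth stays 3 at every scale; a final
projection whose kernel spans the full bin depth (1×1 spatially) collapses to
four material channels, and a softmax constrains each pixel's class
probabilities to sum to one.  Under the documented audit convention —
convolutions, pooling layers, up-convolutions, skip gates and the output
projection counted; normalization and activations not — the default network
has 29 hidden layers.

**Loss.**  `total = FL + λ·MGE` with λ = 0.01.  The focal term is
`−(1/N) Σ_i w_i (1−p_i)^γ t_i log p_i` with γ = 2, probabilities clamped to
[1e-7, 1], and a reduced background weight `w_b` (default 0.25; the weight of
the other classes is 1).  The mean gradient error convolves prediction and
ground truth per class with the 3×3 Sobel masks (reflect padding), forms
gradient-magnitude-squared fields, and averages the squared difference —
promoting edge preservation.

**Backend.**  The network runs on a compact reverse-mode autodiff engine over
numpy arrays written for this package (`pcdmd.nn`): 3D convolution via
im2col + GEMM, spatial transposed convolution and max-pooling, batch
normalization, softmax, fixed-kernel 2D convolution for the Sobel loss, and
an Adam optimizer.  Every operation's gradient is verified against float64
central differences in the test suite.  Tensors carry no batch axis: the
training protocol is batch size 1 throughout.

## Transfer learning

Phase 1 (pre-training) trains the whole network on calibrated simulation
scans with random flips (p = 0.5 per axis), free rotation (bilinear for
images, nearest for labels), and elastic deformation from a Gaussian-smoothed
8×8 displacement grid (default cap 8 px, reduced to 2 px at 64² desk scale in
proportion to the grid).  Phase 2 (fine-tuning) freezes encoder scale 1 —
parameters and batch-norm running statistics — and trains the rest on
real-domain scans with flips and rotations only (no elastic deformation on
real data).  The full protocol is 50 + 100 epochs on 87 + 16 image sets at
Adam lr = 1e-5, batch 1; the desk preset uses 10 + 20 epochs on 30 + 8 scans
at lr = 1e-3 — at desk step counts (≈ 460 updates) the full-protocol learning
rate cannot move the weights appreciably — with a 3-scale, 16-base-channel
network.  All phases are exactly reproducible from (seed, config, manifest).

## Baselines

**MD-LS** solves `min ‖B x − l‖²` per pixel by pseudoinverse; negative
components are clamped to zero with the mask recorded.  **MD-TV** minimizes
the same data term plus `β Σ_m TV(x_m)` (isotropic) by proximal gradient with
fixed step 1/L (L the squared spectral norm of B); the TV proximal operator
is evaluated by Chambolle's algorithm, and an accept-if-decrease safeguard
makes the objective trace monotone non-increasing even though the inner prox
is itself iterative.  At β = 0 the iteration starts at — and therefore stays
on — the unclamped least-squares solution.

Categorical maps for scoring use a threshold/argmax rule that respects the
additive mixture model (the water fraction stays ≈ 1 inside inserts, so a
plain argmax would always return water): background where every map is below
threshold, water where only water clears its threshold, otherwise the argmax
over solute maps normalized by reference concentrations (300 mg/mL Ca,
15 mg/mL I).  The default iodine threshold (3 mg/mL) sits above the spurious
iodine signal that beam hardening induces in water regions of a full-size
phantom (see *Limitations*).

## Evaluation

CNR uses the population standard deviation of a background ROI:
`|ROI_mean − bg_mean| / bg_SD`.  mIoU and mDSC average per-class
intersection-over-union and Dice over the four classes; a class absent from
both maps scores 1 (logged in every report) so water-only phantoms are not
penalized.  R² pools all material channels and pixels,
`1 − Σ(gt−pred)²/Σ(gt−mean(gt))²`, computed on one-hot maps when no
continuous ground truth is supplied (flagged in the report).  DSC and IoU
satisfy `DSC = 2·IoU/(1+IoU)` per class, which the suite verifies on random
maps.

## Numerical choices

* HVL bisection on [0, 100] mm Al; inner HVL measurement by Brent's method.
* Calibration fits: starts b ∈ {0.1, 1, 10} with (a, c) solved in closed form
  per start; gradient tolerance 1e-10; the fit falls back to the constant
  model when it cannot beat it.
* Probability clamping at 1e-7 before logarithms keeps the focal loss finite
  on saturated outputs.
* Argmax ties break toward the lower class index everywhere.
* Photon starvation: zero-count rays are clamped to 1 count and logged.
* Inputs whose spatial size is not divisible by 2^(scales−1) are zero-padded
  and cropped back after the head.

## What the synthetic data do and do not show

The generator reproduces the physics that drives the method: spectrum-
weighted bin contrast including the iodine K-edge, beam hardening, Poisson
noise, FBP texture, partial volume at insert boundaries, and a monotone
sim-to-real nonlinearity with noise.  It does not model detector spectral
distortions (pulse pileup, charge sharing), scatter, anatomical shapes and
textures, or motion.  Passing tests therefore demonstrate that the pipeline
learns and transfers under controlled spectral physics, not clinical
performance on scanner data.

## Known limitations

* **Intra-bin beam hardening defeats linear decomposition of dense calcium.**
  Within bin 1 (30–50 keV) the calcium LAC varies threefold, so a
  300–1000 mg/mL insert depresses its reconstructed bin-1 value ~12% below
  the linear basis prediction; per-pixel LS misattributes that deficit mostly
  to the K-edge-tilted iodine channel.  This is the known failure mode of
  image-domain MD-LS that the learned method is meant to beat; consequently
  the LS chain-sanity test uses a one-line-per-bin acquisition (where the
  linear model is exact) and the polychromatic regime is evaluated through
  the method comparison.  Similarly, in water regions of a full-size phantom
  hardening reads as ~1–2.5 mg/mL of spurious iodine, which sets the
  categorical iodine threshold.
* The layer-count audit convention is the package's own; whether
  normalization layers count as "hidden layers" is not externally defined.
* Batch-size-1 batch normalization normalizes each sample by its own
  statistics during training; inference uses running averages.
* The desk-scale benchmark (64², 120 views) inherits coarse pixels: inserts
  are 3–6 px in radius and boundary pixels dominate small inserts, which
  bounds the achievable IoU for the smallest iodine inserts.
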