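# Methods

`taskbed` is a virtual-imaging test bed for studying how task information —
the detectability of a signal by a numerical observer — survives or is lost
when CT images are denoised by a supervised CNN, and how a task-informed
fine-tuning stage can trade fidelity for task performance. This note
records the models, the numerical choices, and the scale at which the
package's own studies run.

## Object model

Backgrounds follow the stationary *lumpy background* model standard in the
model-observer literature: a constant offset `dc_offset` plus a
Poisson-distributed number (`mean_lump_count`) of Gaussian lumps with
centres uniform over the image. Lumps are evaluated with the minimal torus
(wrap-around) distance, which makes the process exactly stationary: the
ensemble pixel mean is `dc_offset + mean_lump_count * lump_integral / area`
at every pixel, a closed form the tests check by brute-force averaging.

Signals are compact Gaussian blobs inserted additively, with a location law
that is fixed, uniform over a disc of radius `r`, or one of `J` discrete
sites (the detection-localization case). Pixel values play the role of
per-mm attenuation; images are in units of mm^-1 and the grid spacing is
1 mm unless configured otherwise.

Default parameters (background: 30 lumps of width 6 px and amplitude 0.035
on dc 0.05; signal: width 1 px, amplitude 0.4) were calibrated once so
that, at the default flux, the observer AUCs fall in the 0.55–0.95
operating band: the SLNN-NO reads the low-dose images at ≈0.7–0.8 AUC, the
MSE-pretrained denoiser's outputs at ≈0.72, and strongly task-weighted
fine-tuning reaches ≈0.98. The signal is deliberately *fine* relative to
the background texture: high-spatial-frequency content is what an
MSE-optimal smoother sacrifices first, which is the regime in which
task-informed training has information to recover.

## Imaging chain

The forward operator is a discrete-to-discrete fan-beam transform: a source
on a 400 mm circle, a flat detector of equispaced elements (default 512 ×
0.8 mm) 400 mm on the far side, 256 evenly spaced views over 360°. Each
sinogram entry is the line integral along the source-to-element ray,
evaluated by equidistant sampling at half-pixel steps with bilinear
interpolation. When the sampling footprint is small enough the projector is
materialized once as a sparse matrix, so whole ensembles are projected as a
single sparse product; otherwise the identical sampling scheme is evaluated
view by view. The exact transpose of the projector is also exposed; the
inner-product identity ⟨Hf, g⟩ = ⟨f, Hᵀg⟩ holds to floating precision and
documents the discretization.

Low-dose data follow the exponential transmission model
`g = T^-1(Poi(T(Hf)))` with `T(x) = I0·exp(−x)`; the incident flux defaults
to `I0 = e^11` photons per ray. Poisson draws of zero counts are clamped to
a configurable floor (1 count) before the log, so opaque paths degrade
gracefully instead of crashing. Note that `E[log(I0/N)]` carries an
`O(1/2N)` bias: at the weak-attenuation end (counts in the thousands) it is
far below the noise and the transform is mean-preserving to Monte-Carlo
precision, while at strongly attenuating paths the bias is real physics and
is *not* corrected.

Reconstruction is full-scan fan-beam FBP for a flat equidistant detector:
cosine weighting, a Ram-Lak (band-limited ramp) kernel applied in the
frequency domain with zero-padding to the next power of two and no
apodization window, and distance-weighted back-projection with the
half-scan factor for the doubly covered 360° orbit.

One geometric constraint worth recording: with the default detector
(512 × 0.8 mm at magnification 2) the untruncated field of view at the
isocenter is 204.8 mm across, so the largest square grid that avoids
projection truncation has side 204.8/√2 ≈ 144 mm. The default full-field
grid is therefore 128 — a 160 grid looks innocuous but puts its corners
outside every detector row and visibly corrupts the reconstruction
(interior NRMSE 0.074 vs 0.003 at 128).

## Denoiser and training

The denoiser is the canonical depth-`D` CNN: Conv+ReLU, then `D−3`
Conv+BatchNorm+ReLU blocks, Conv+BatchNorm, and a final 1-channel Conv, all
3×3 with same-size padding, fully convolutional so any side ≥ 16 works. The
network, batch normalization, backpropagation, and Adam are implemented
directly in numpy: activations use a channel-leading layout `(C, B, H, W)`
so each convolution is one large GEMM via im2col, and the input gradient of
a same-padded stride-1 convolution is itself a convolution with the flipped
kernels, so no scatter operation is needed. Gradients are validated against
central finite differences in the test suite.

Pretraining minimizes the per-batch mean of the squared L2 distance between
output and noiseless target on minibatches balanced 50/50 between
signal-present and signal-absent pairs; the weight state with the best
validation MSE is kept. Weight initialization is He-style fan-in scaling
with a recorded seed.

## Hybrid-loss fine-tuning

Fine-tuning appends a single-layer observer to the denoiser output and
minimizes

    L = (1 − λ)·L_p + λ·L_t,   λ ∈ [0, 1],

jointly over the observer weights and the last `n_train` convolutional
layers; everything earlier is frozen *bit-exactly*, including batch-norm
running statistics (frozen layers run in inference mode during
fine-tuning). `L_p` is the MSE term; `L_t` is binary cross-entropy
(SLNN-NO), the quadratic Hotelling-approximating loss (SLNN-HO, whose
minimizer over the observer weights is the batch Hotelling template
`K^−1Δf̄` — verified analytically and by optimization in the tests), or
categorical cross-entropy over `J+1` classes for detection-localization.

Two conventions are deliberate package choices:

* both loss terms are reduced to per-batch means before mixing, so λ's
  meaning does not depend on the batch size (the standalone loss functions
  still report the literature sums);
* the class-conditional means inside the Hotelling loss come from the
  current balanced minibatch, and one Adam instance with a single learning
  rate updates the observer and the trainable layers jointly.

The SLNN-HO template starts at zero (its loss then starts exactly at zero);
sigmoid/softmax observers start with fan-scaled random weights and zero
biases. `L_p` and `L_t` are computed on the same minibatch stream.

## Observers for evaluation

* **HO** — template `w = K^−1Δf̄` with `K = (K0+K1)/2` from sample
  covariances (divisor n−1), solved by a symmetric eigendecomposition; a
  singular or ill-conditioned `K` (condition number beyond 1e12) raises an
  error directing the caller to the regularized variant.
* **RHO** — truncated-SVD pseudo-inverse keeping singular values above
  `α·σ_max`; `α` is selected from {1e−1 … 1e−7} by validation AUC.
* **DOG-CHO** — ten radial difference-of-Gaussians frequency channels
  `C_j(ρ) = exp(−½(ρ/(Qσ_j))²) − exp(−½(ρ/σ_j)²)`, `σ_j = σ0·α^j` with
  σ0 = 0.005 cycles/pixel, α = 1.4, Q = 1.67, sampled on the discrete FFT
  grid and inverse-transformed to spatial channel vectors; internal channel
  noise is Gaussian with covariance `ε·diag(K_v)` (ε = 2.5) drawn from a
  dedicated recorded seed. With identity channels and ε = 0 the CHO reduces
  exactly to the HO.
* **SLNN-NO / softmax SLNN** — single fully connected layer (+bias) with
  sigmoid or softmax, trained with Adam; the evaluation observer is always
  trained on *denoised* images, independently of any observer used inside
  fine-tuning. For detection-localization the scalar detection statistic is
  `1 − P(class 0)` and localization accuracy (argmax over signal classes)
  is reported separately; an LROC-style figure of merit is not implemented.

AUC is the nonparametric Mann-Whitney estimate with ties counted one half
and the Hanley-McNeil standard error (a proper binormal ROC fit is out of
scope); the test suite pins the estimator to exhaustive pair counting. On
shared-covariance Gaussian data the Hotelling statistic has equal class
variances SNR² and mean separation SNR², so its AUC has the closed form
Φ(SNR/√2) — the analytic anchor the observer stack is tested against.
SSIM uses the standard 11-pixel Gaussian window (σ = 1.5, K1 = 0.01,
K2 = 0.03) with the dynamic range taken from the reference ensemble.

The covariance-spectrum diagnostic reports the singular values of the
denoised-image covariance and the condition ratio `σ_max/σ_k` at a
configured rank (default k = 100, within the rank of the empirical
covariance at the default test-set size).

## Study designs and scale

Experiments follow a fixed arm protocol — simulate paired data at the full
field, crop the ROI, pretrain, fine-tune at (λ, n_train), train an
independent evaluation observer on the arm's denoised training images,
score AUC/RMSE/SSIM/condition ratio on the denoised test images. Matched
reference arms share seeds, sample sizes, the pretrained model, and the
observer protocol, so any gap is attributable to the fine-tuning task
alone. Reported trends are medians over five seeds.

All studies run at the `TINY` profile, a deliberate reduction sized for a
single CPU with the numpy training stack: ROI 32 (full field 48), 6 filters,
depth 7, 128 training pairs per class (64 validation, 256 test per class),
a 64-view × 96-element geometry, Adam at 3e-3 for 60 pretraining and 20
fine-tuning epochs, and the full λ grid {0.01, 0.1, 0.3, 0.5, 0.7, 0.9,
0.99} with the last three layers trainable. The `DESK` profile holds a
larger reference configuration (ROI 64, 64 filters, the full
256 × 512 scanner geometry, learning rate 1e-4) for users with hours of CPU or a port
of the training loop to an accelerated backend. The raised learning rate at
`TINY` scale compensates for the much smaller step budget; at 1e-4 the
small-profile networks would be far from convergence.

The task-shift study (fixed-location source vs uniform-disc targets) uses
mismatch radii {2, 4, 6} pixels — the side-32 scaling of a {4, 8, 12} grid
at side 64, matching the relative mismatch range of the original design —
and runs at λ = 0.99. Two scale effects force these choices: a disc radius
of 12 at ROI 32 makes the target task undetectable for every arm (AUC ≈
0.5), so no shift gap can exist there; and at λ = 0.7 the task term's
imprint on the small denoiser is within evaluation noise, whereas at 0.99
the shifted-vs-reference gap is clearly measurable and grows monotonically
with the mismatch radius.

What the synthetic studies do and do not show: the generator reproduces the
*statistical roles* of the real study — BKS background variability, SKS
location randomness, paired normal/low-dose images through a physical noise
model — but not anatomical texture, nodule morphology, or the
1e4-image/1.4e4-dimensional covariance regime. Passing trends here
demonstrate the mechanics and direction of the method (fidelity/task
trade-off controlled by λ, recovery of task information by constrained
fine-tuning, degradation under task-shift growing with mismatch), not the
original absolute AUC/RMSE values, which depend on the clinical data.

## Known limitations

* The one-CPU numpy trainer makes large profiles expensive; `DESK`-scale
  runs are hours, not minutes.
* Fine-tuning at λ close to 1 can effectively abandon fidelity (RMSE grows
  several-fold) — faithful to the hybrid objective, but such arms should be
  read as task-optimal rather than useful denoisers.
* The MSE-pretrained models at `TINY` scale stop short of full convergence;
  a λ ≈ 0 fine-tune therefore still improves RMSE slightly rather than
  leaving it exactly unchanged.
* Detection-localization evaluation uses plain detection ROC plus a
  separate localization accuracy, not an LROC curve.
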