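# Methods

## Problem setting

Synchrotron X-ray tomography of radiation-sensitive samples trades signal
for dose: short exposures damage the sample less but give noisy
projections, and the noise propagates into the reconstruction.  The method
implemented here learns, for a *single* sample, the mapping from
short-exposure to long-exposure projections using only a few angle pairs,
then applies that mapping to the whole angular scan before reconstruction.
Because training and inference data come from the same object, no explicit
noise model is required.

## Synthetic benchmark

The generator emulates the evaluation phantom: a solid cube (gray value
0.3) in empty space (0.0) containing spherical particles (1.0) with
diameters uniform on [4, 20] voxels and centers uniform inside the cube.
The cube edge is `floor(size/sqrt(2))` so its rotated shadow always fits a
detector as wide as the volume.  Full-scale conditions are a 512^3 volume,
1000 spheres, and 721 equispaced projection angles over [0, 180] degrees;
Gaussian noise at 5-30% emulates shorter exposures; the network trains on
the projection pairs at 0 and 45 degrees.

Reduced-scale surrogates (`benchmark_params(size)`) preserve two densities:
spheres per voxel (`n_spheres = 1000 * (size/512)^3`) and angles per
detector pixel (`n_angles = 720 * size/512 + 1`).  Sphere diameters are
*not* scaled (they are a physical feature size), so the particle volume
fraction (~1%) matches the full-scale benchmark at every size.

**Noise convention.**  "x% noise" is additive zero-mean Gaussian noise with
standard deviation `x% * (max - min)` of the whole clean projection stack,
identical for every projection.  A percentage noise level needs a
reference scale and the global range is the only choice that treats all
angles identically and is invariant to the linear scale of the line
integrals.  Per-projection ranges differ by <2% on this phantom, so the
distinction is minor here.

**What the surrogate does and does not show.**  Line-integral magnitudes
grow linearly with the volume edge while reconstructed gray values stay at
0/0.3/1, so reconstruction noise at fixed percentage level grows with
scale (measured mean slice PSNR of the 30%-noise reconstruction against
the clean one: 15.1 dB at 64^3, 13.8 at 128^3, 10.5 at 256^3, ~7.5
extrapolated at 512^3).  Relative comparisons (enhanced vs noisy, CNN vs
baselines) transfer across scales; absolute PSNR values do not.  The
simulator also omits several features of real measurements: photon
(Poisson) statistics, detector blur and fixed-pattern noise, beam drift
between exposures, and rotation-center error.

## Forward projection and reconstruction

Both directions of the parallel-beam Radon transform are computed in the
Fourier domain via the central-slice theorem, so that the whole volume is
processed slice-parallel:

* the 2-D spectrum of each slice lives on a 2x zero-padded grid;
* polar samples along each angle's central slice are related to that grid
  by a width-4 Kaiser-Bessel kernel (Beatty's beta for oversampling 2)
  with analytic sinh-form deapodization;
* the resampling geometry is independent of the slice, so it is built once
  as a sparse matrix per (detector width, angle list) and applied to all
  slices as one sparse-dense product.

Reconstruction is the same operator run in the scatter direction with the
polar samples pre-weighted by a windowed ramp — i.e. GridRec.  The default
window is Parzen (de la Vallee Poussin) applied to frequencies relative to
the detector Nyquist with cutoff 1.0; `ramp`, `shepp`, `cosine` and `hann`
are also available.  Angle weights are trapezoidal in radians (a stack
containing both 0 and 180 degrees therefore counts the duplicated view at
half weight).  The rotation axis sits at detector index `N//2` to match
the projector; a `center` argument shifts measured sinograms by a Fourier
phase ramp.  Amplitude is calibrated: a unit disk reconstructs to interior
minus exterior contrast of 1.000 +- 0.03 with a ramp filter, and
reconstructions of the phantom recover its gray levels directly (no
rescaling).

Accuracy notes: the Kaiser-Bessel interpolation is exact on axis-aligned
angles (the 0-degree projection equals the column sum to <0.5%) and
agrees with direct rotate-and-sum ray integration to ~1% away from sharp
edges.  No circular field-of-view mask is applied; corner voxels outside
the inscribed circle carry the usual filtered-backprojection junk and are
included in histograms (as they are in common practice).

## Normalization and patching

Each projection is normalized in two steps: standardize (subtract mean,
divide by std), then affinely rescale the result to [0, 1].  The recorded
parameters invert the composite exactly (round-trip error <= 1e-6).
During training the *short-exposure* image's parameters are applied to
both members of a pair, so the target is the long-exposure image expressed
in the input's normalized coordinates; de-normalizing the network output
with the input's parameters therefore returns the enhanced projection on
the long-exposure physical scale.  (Normalizing each side independently
would bake the noise-dependent range inflation into the output scale and
corrupt downstream PSNR/SSIM.)

Patches are square, edge a multiple of 8 (the encoder halves the spatial
size three times), extracted on a stride grid with the final anchor
clamped to the image edge so every pixel is covered; reassembly averages
overlapping patches.  Defaults: patch 64, training stride 16, inference
stride = patch/2.  At the 128^3 surrogate the same overlap fractions are
kept at half size: patch 32, training stride 8, inference stride 16.

## Network and objective

Encoder: 8 convolutional layers, 3x3 kernels, kernel counts
(16, 16, 32, 32, 32, 64, 64, 64) with stride 2 at layers 2, 4 and 6,
followed by a shape-preserving fully connected bottleneck on the flattened
(E/8)^2 x 64 encoding.  Decoder: 9 transpose-convolutional layers, counts
(64, 64, 32, 32, 32, 16, 16, 16, 1) with stride 2 at layers 3, 5 and 7.
After each upsampling deconvolution the feature maps are concatenated with
the encoder output of the same spatial scale (encoder layers 5, 3, 1), so
the decoder sees every resolution of the input.  ReLU everywhere,
including the single-kernel output layer.  He-normal initialization,
deterministic per seed.

The training objective is `1/PSNR` with `PSNR = 10 log10(i_max / MSE)`
evaluated per mini-batch on normalized patches with `i_max = 1` (at unit
peak the printed unsquared form coincides with the conventional squared
definition).  MSE is floored at 1e-12 and PSNR clamped at 0.5 dB; in the
clamped region the gradient falls back to plain MSE descent so early
catastrophic batches cannot produce a sign-flipped objective.  Minimizing
1/PSNR is a monotone transform of minimizing MSE at fixed i_max; the
practical difference is an adaptive step-size scaling of the gradient.

Everything is plain NumPy: convolutions run as im2col/GEMM, the transpose
convolution is implemented as the exact adjoint of the strided convolution
(zero-stuffing plus stride-1 convolution with the flipped kernel), and
gradients are hand-derived and verified against finite differences in the
test suite.  Optimizer: Adam, learning rate 1e-3, batch 32 (16 at
surrogate scale, where the patch set is small and more update steps per
epoch help), 10% of patches held out for the logged validation MSE.  One
model is trained per noise level; a joint model is possible by passing
pairs from several levels.

## Evaluation

* PSNR: `10 log10(data_range^2 / MSE)`, capped at 100 dB for identical
  images; reconstruction comparisons use `data_range = 1` (the phantom's
  gray scale).
* SSIM: Gaussian-windowed (11x11, sigma 1.5), K1 = 0.01, K2 = 0.03; the
  global score is the mean over valid windows, and `ssim_map` returns the
  full-size per-pixel map.
* Volume reports are slice-wise with means and standard deviations across
  slices.
* Histogram modes: 256 bins over the volume's range, smoothed with a
  5-bin moving average; local maxima (histogram edges included) with
  prominence >= 1% of the tallest smoothed bin count as modes.  The rule
  is deliberately fixed so that "the phases are separable" is a testable
  statement.  At desk scale it is sensitive: clean reconstructions of the
  sharp-edged phantom show small Gibbs-plateau bumps (~5% of the peak
  count) between the physical phases, and the particle phase (~1% of
  voxels) hovers near the prominence threshold, so exact mode counts at
  small sizes differ from full-scale behaviour (see the ledger of known
  limitations below).

## Baselines

Median filtering (sliding window, reflected edges) and Rudin-Osher-Fatemi
total variation via Chambolle's dual projection scheme (100 iterations),
each applied per projection.  Hyperparameters were fixed once by a grid
search maximizing each baseline's own mean SSIM against the clean
projections on the 10%-noise surrogate — median window {3, 5, 7} -> 7;
TV weight {0.05, 0.1, 0.2, 0.3, 0.5} on range-normalized images -> 0.2 —
so the comparison is as favourable to the baselines as those families
allow.  The TV weight acts on the image normalized by its own range,
making the default transferable across exposure scales.

## Problem sizes used by the test suite and acceptance script

The acceptance script runs the full-size benchmark (512^3, 1000 spheres,
721 angles, 30% noise, no training) in a few minutes on one CPU thanks to
the slice-parallel GridRec.  The test suite exercises the learned pipeline
at the 128^3 surrogate (181 angles, patch 32, training stride 8, 20
epochs per noise level; the 10% model instead uses stride 4 — a four-fold
denser patch set, since training-set size is the lever this method lives
on — and 35 epochs, and also backs the
convergence and baseline-comparison checks) and the no-CNN benchmark at
256^3, and uses 48-96^3 volumes for unit-level oracles.

## Known limitations

* Gaussian noise only; no Poisson/photon statistics, no detector model.
* Parallel-beam geometry only; no cone/fan beam, no phase contrast.
* Absolute noisy-reconstruction PSNR depends strongly on the percentage
  noise convention and the filter window; comparisons against published
  absolute values carry that convention uncertainty (the window choice
  alone moves the figure by 4-14 dB).
* The histogram mode-count rule is scale-sensitive as described above.
* No pre-trained weights are shipped; transfer across samples is out of
  scope.
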