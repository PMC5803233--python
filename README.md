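# tomoenhance

Low-dose (short-exposure) X-ray tomography gives noisy projections; long
exposures give clean data but damage radiation-sensitive samples.
`tomoenhance` implements a projection-domain enhancement strategy for
parallel-beam tomography: acquire long exposures at only two or three
angles, train an encoder-decoder convolutional network `f : I_s(a) -> I_l(a)`
on overlapping patches of those pairs, apply `f` to the entire
short-exposure scan, and reconstruct the enhanced stack.  Because training
and inference data come from the same object, a few projection pairs carry
enough local structure to enhance the whole scan, and no explicit noise
model is needed.

The package is aimed at synchrotron/TXM users and method developers and
contains:

* a synthetic three-phase benchmark (sphere-in-cube phantom, gray values
  0/0.3/1, Radon projections, percentage-scaled Gaussian noise);
* two-step normalization (standardize, then min-max to [0, 1]) and
  overlapping patch extraction/reassembly;
* the 8-conv encoder / FC bottleneck / 9-deconv decoder network with
  scale-matched skip merges, trained by minimizing `1/PSNR` with
  `PSNR = 10 log10(i_max / MSE)` — pure NumPy, no GPU required;
* GridRec reconstruction (Fourier regridding with a Kaiser-Bessel kernel)
  with a Parzen-windowed ramp filter;
* PSNR / SSIM / SSIM-map / histogram-mode evaluation, and median-filter and
  total-variation (Chambolle) baselines;
* multi-page TIFF and HDF5 Scientific-Data-Exchange I/O, a YAML-configured
  end-to-end pipeline, and a thin `tomoenhance` CLI.

## Worked example

`examples/03_reconstruct_and_evaluate.py` simulates a 96^3 benchmark,
reconstructs clean and noisy stacks and prints:

```
noise   5%: PSNR  29.13 +- 0.13 dB | SSIM 0.481 +- 0.141 | histogram modes 3
noise  30%: PSNR  13.57 +- 0.13 dB | SSIM 0.055 +- 0.034 | histogram modes 1
```

i.e. at 5% noise the three gray-value phases are still separable (3
histogram modes), while at 30% the reconstruction collapses to a single
mode and thresholding becomes impossible.  `examples/02_train_and_enhance.py`
then trains the network on the 0/45-degree pairs only and evaluates an
angle it never saw:

```
epoch   1: train MSE 2.08e-02 val MSE 1.71e-02
epoch  13: train MSE 1.79e-03 val MSE 1.77e-03

projection at 90 deg (unseen during training):
  SSIM(noisy,    clean) = 0.395
  SSIM(enhanced, clean) = 0.574
```

The enhanced projection is substantially closer to the long-exposure
reference than the noisy input.  At the 128^3 surrogate scale (the size
used by the test suite), 20 epochs of training lift the 30%-noise
reconstruction from 13.8 dB / 0.046 SSIM to 27.3 dB / 0.43 SSIM relative
to the clean reconstruction.

The same operations are available from the shell:

```bash
tomoenhance simulate --size 128 --seed 0 --out runs/sim
tomoenhance train --low runs/sim/P_n10.tif --high runs/sim/P_o.tif \
                  --angles 0,45 --patch 32 --stride 8 --out runs/model.npz
tomoenhance enhance --model runs/model.npz --in runs/sim/P_n10.tif --out runs/P_e.tif
tomoenhance reconstruct --in runs/P_e.tif --filter parzen --out runs/R_e.tif
tomoenhance evaluate --test runs/R_e.tif --ref runs/R_o.tif --report report.json
tomoenhance run --config config.yaml      # the whole pipeline in one go
```

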