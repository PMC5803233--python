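"""Reconstruct noisy and clean stacks and compare volume quality.

GridRec (Fourier-grid filtered backprojection with a Parzen window)
reconstructs one volume per stack; the report gives slice-wise PSNR/SSIM of
the noisy reconstruction against the clean one, and the histogram mode
count shows whether the three gray-value phases are still separable.
"""

import numpy as np

from tomoenhance import (
    add_noise,
    benchmark_params,
    forward_project,
    generate_phantom,
    histogram_modes,
    reconstruct,
    volume_report,
)

params = benchmark_params(96)
phantom = generate_phantom(params.size, params.n_spheres, seed=0)
p_o = forward_project(phantom, np.linspace(0, 180, params.n_angles))
r_o = reconstruct(p_o, filter_name="parzen")

for level in (0.05, 0.30):
    p_n = add_noise(p_o, level, seed=1)
    r_n = reconstruct(p_n, filter_name="parzen")
    rep = volume_report(r_n, r_o, data_range=1.0)
    _, _, modes = histogram_modes(r_n)
    print(f"noise {level:4.0%}: PSNR {rep.psnr_mean:6.2f} +- {rep.psnr_std:.2f} dB | "
          f"SSIM {rep.ssim_mean:.3f} +- {rep.ssim_std:.3f} | histogram modes {modes}")
print("PSNR/SSIM measure closeness to the clean reconstruction; a single "
      "histogram mode means the phases can no longer be thresholded")
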