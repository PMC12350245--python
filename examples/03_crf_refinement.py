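"""CRF spatial refinement: cleaning a noisy probability map.

A square region with salt-and-pepper label noise is refined by mean-field
inference under a Potts pairwise potential; isolated single-pixel islands
disappear.  On a tiny 2x2 instance the exact enumeration posterior and the
partition value Z are also computed.
"""

import numpy as np
from scipy import ndimage

from specseg.crf import (
    CRFParams,
    EnergyModel,
    exact_posterior,
    mean_field_refine,
)

rng = np.random.default_rng(42)
truth = np.zeros((16, 16), dtype=int)
truth[4:12, 4:12] = 1
noisy = truth.copy()
flips = rng.random(truth.shape) < 0.08
noisy[flips] = 1 - noisy[flips]
probs = np.where(noisy[..., None] == np.arange(2), 0.9, 0.1)


def islands(arr):
    return sum(ndimage.label(arr == v)[1] for v in (0, 1))


refined = np.argmax(
    mean_field_refine(probs, np.zeros((16, 16, 1)),
                      CRFParams(beta2=3.0, n_iters=10)),
    axis=2,
)
print(f"label islands before refinement: {islands(noisy)}")
print(f"label islands after refinement:  {islands(refined)}")
print(f"pixels recovered to ground truth: {np.mean(refined == truth):.3f}"
      f" (noisy input agreed on {np.mean(noisy == truth):.3f})")

# exact posterior on an enumerable 2x2 binary instance
small = rng.dirichlet(np.ones(2), size=(2, 2))
model = EnergyModel.from_probabilities(small, np.zeros((2, 2, 1)),
                                       CRFParams(beta2=1.0))
table, z = exact_posterior(model)
best = max(table, key=table.get)
print(f"\n2x2 exact posterior: Z = {z:.4f}, sum of probabilities ="
      f" {sum(table.values()):.12f}")
print(f"most probable labeling {tuple(int(v) for v in best)} "
      f"with P = {table[best]:.3f}")
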