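"""Every term of the composite training objective on small closed-form inputs.

The printed values can be checked by hand: identical contrastive embeddings
give B ln 2, a chance-level discriminator gives 2 ln(1/2), uniform binary
segmentation gives ln 2, and unit parts under the default weights
(lambda_cls=1, lambda_DA=1, lambda_CL=0.5, lambda_KR=1, lambda_UC=0.2)
compose to 4.7.
"""

import numpy as np

from specseg import losses as L
from specseg.phantoms import AnatomicalPriorSet

w = L.LossWeights()
print(f"weights: DA={w.lambda_da} CL={w.lambda_cl} KR={w.lambda_kr} "
      f"UC={w.lambda_uc} tau={w.tau}")

probs = np.full((4, 4, 2), 0.5)
seg = L.seg_loss(probs, np.zeros((4, 4), int))
print(f"seg loss, uniform binary predictions: {seg:.4f} (= ln 2)")

e = np.ones((2, 3))
cl = L.contrastive_loss(L.EmbeddingBatch(e, e.copy()), w.tau)
print(f"contrastive loss, identical embeddings (B=2): {cl:.4f} (= 2 ln 2)")

disc = L.discriminator_loss(np.full(4, 0.5), np.full(4, 0.5))
print(f"discriminator at chance: {disc:.4f} (= -2 ln 2)")

da = L.domain_alignment_loss(
    L.DomainBatch(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]))
)
print(f"domain alignment, features (0,0) vs (3,4): {da:.1f} (= 5^2)")

prior = AnatomicalPriorSet(pairs=((0, 1, 5.0),))
kr = L.knowledge_reg_loss({0: (0.0, 0.0), 1: (0.0, 3.0)}, prior)
print(f"knowledge regularization, distance 3 vs prior 5: {kr:.1f} (= (5-3)^2)")

uc = L.uncertainty_loss(np.full((2, 2, 2), 0.5), np.array([[0, 0], [1, 1]]))
print(f"uncertainty surrogate, half-confident half-correct: {uc:.2f}")

report = L.total_loss(1, 1, 1, 1, 1, 1, 1, w)
print(f"total objective with unit parts: {report.total:.2f}")
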