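"""Domain adaptation on a synthetic acquisition shift.

Target phantoms carry a gain-2 / offset-0.1 per-band affine shift and no
labels.  Training once with the alignment + adversarial terms and once
without, then measuring the mean pairwise squared distance between pooled
source and target features, shows the adaptation machinery shrinking the
domain gap.
"""

import tempfile
from pathlib import Path

from specseg.losses import LossWeights
from specseg.network import NetworkConfig
from specseg.phantoms import PhantomConfig
from specseg.pipeline import (
    TrainConfig,
    materialize_phantom_dataset,
    measure_domain_alignment,
    train,
)

pcfg = PhantomConfig(height=16, width=16, n_bands=4,
                     lesion_radius_range=(2.0, 3.5),
                     signature_centers=(0.5, 2.5),
                     domain_gain=2.0, domain_offset=0.1, seed=33)
net = NetworkConfig(n_scales=2, channels=(6, 8), fuse_channels=6,
                    n_classes=2, n_image_classes=2,
                    spectral_encoder="lstm", spectral_hidden=4)

with tempfile.TemporaryDirectory() as tmp:
    manifest, _ = materialize_phantom_dataset(Path(tmp), pcfg,
                                              n_source=32, n_target=32)
    ck_on, _ = train(manifest, net,
                     TrainConfig.desk(batch_size=8, max_epochs=12, seed=0))
    ck_off, _ = train(manifest, net, TrainConfig.desk(
        batch_size=8, max_epochs=12, seed=0, adversarial=False,
        weights=LossWeights(lambda_da=0.0, lambda_adv=0.0)))

    gap_on = measure_domain_alignment(ck_on, manifest)
    gap_off = measure_domain_alignment(ck_off, manifest)
    print(f"domain feature gap with adaptation:    {gap_on:.4f}")
    print(f"domain feature gap without adaptation: {gap_off:.4f}")
    print(f"reduction factor: {gap_off / gap_on:.1f}x "
          "(lower gap = domain-invariant features)")
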