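"""One forward pass: pyramid, gated fusion, attention, and the two heads.

Prints the learned gate weights (softmax over scales), attention-map range,
and verifies that both heads emit normalized probabilities.
"""

from specseg.network import NetworkConfig, SegmentationModel, predict
from specseg.phantoms import PhantomConfig, generate_phantom

pcfg = PhantomConfig(seed=3)
phantom = generate_phantom(pcfg, class_label=1, domain="source")

config = NetworkConfig(n_classes=2, n_image_classes=2,
                       spectral_encoder="lstm", spectral_hidden=8)
model = SegmentationModel(config, n_bands=pcfg.n_bands, seed=0)

out = model.forward(phantom.image.data[None])
print(f"gate weights alpha (sum {out['alpha'].sum():.3f}): {out['alpha'].round(3)}")
a = out["attention"].attention_map
print(f"attention map range: ({a.min():.3f}, {a.max():.3f})  -- strictly in (0,1)")

seg_probs, cls_probs = predict(phantom.image, config, model.params)
print(f"per-pixel probability sums: {seg_probs.sum(axis=2).min():.6f}"
      f" .. {seg_probs.sum(axis=2).max():.6f}")
print(f"image-class probabilities:  {cls_probs.round(3)} (sum {cls_probs.sum():.3f})")
print("(untrained weights: the maps are near-uniform until training)")
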