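"""Multi-scale gated segmentation network with spectral sequence encoding.

Architecture (the package's documented interpretation of a CNN + sequence
encoder + attention hybrid):

1. a convolutional pyramid over the image — level 1 at full resolution,
   each subsequent level downsampled by the stride schedule
   (``F_l = sigma(W_l * F_{l-1} + b_l)``);
2. softmax-gated fusion of the pyramid levels: every level is projected to a
   common channel width by a 1x1 convolution, coarser levels are bilinearly
   upsampled to the finest grid, and the levels are combined with weights
   ``alpha_m = softmax(gamma)_m`` (free scalar gate logits, one per scale);
3. a spectral sequence encoder that treats each pixel's band vector as an
   ordered length-C sequence (bidirectional LSTM or transformer encoder, or
   ``none`` to bypass); its per-pixel features are concatenated with the
   fused spatial features;
4. sigmoid attention ``A = sigmoid(W_A * F + b_A)`` applied post-fusion,
   ``F_att = A ⊙ F``;
5. a 1x1-conv segmentation head (per-pixel softmax over K labels) and a
   pooled linear classification head (softmax over image classes).

All computation runs on :mod:`specseg.autodiff` tensors so the training loop
can differentiate end to end.  Argmax ties break toward the smallest class
index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, NumericError, ShapeError
from .spectral_io import SpectralImage

__all__ = [
    "ConvLevelParams",
    "FeaturePyramid",
    "AttentionState",
    "NetworkConfig",
    "SegmentationModel",
    "encode_level",
    "build_pyramid",
    "gated_fuse",
    "attention_aggregate",
    "encode_spectral_sequence",
    "predict",
    "bilinear_resize",
]

_ACTIVATIONS = ("relu", "leaky_relu")


@dataclass
class ConvLevelParams:
    """One convolutional level: kernel, bias, activation tag."""

    weight: Tensor  # (kh, kw, cin, cout)
    bias: Tensor  # (cout,)
    activation: str = "relu"

    def __post_init__(self):
        if not isinstance(self.weight, Tensor):
            self.weight = Tensor(self.weight, requires_grad=True)
        if not isinstance(self.bias, Tensor):
            self.bias = Tensor(self.bias, requires_grad=True)
        kh, kw = self.weight.shape[:2]
        if kh % 2 == 0 or kw % 2 == 0:
            raise ConfigurationError("kernel spatial dims must be odd")
        if self.activation not in _ACTIVATIONS:
            raise ConfigurationError(
                f"activation must be one of {_ACTIVATIONS}, got {self.activation!r}"
            )


@dataclass
class FeaturePyramid:
    """Per-scale feature maps plus gate logits and (after fusion) F_multi."""

    levels: list
    gate_logits: Tensor
    fused: Tensor | None = None
    alpha: np.ndarray | None = None

    def __post_init__(self):
        if len(self.levels) < 1:
            raise ConfigurationError("a pyramid needs at least one level")
        if not isinstance(self.gate_logits, Tensor):
            self.gate_logits = Tensor(self.gate_logits, requires_grad=True)
        if self.gate_logits.data.shape != (len(self.levels),):
            raise ShapeError("need exactly one gate logit per pyramid level")


@dataclass
class AttentionState:
    """Attention kernel/bias plus the computed map and attended features."""

    weight: Tensor  # (1, 1, C, 1) by default
    bias: Tensor  # (1,)
    attention_map: np.ndarray | None = None
    f_att: Tensor | None = None

    def __post_init__(self):
        if not isinstance(self.weight, Tensor):
            self.weight = Tensor(self.weight, requires_grad=True)
        if not isinstance(self.bias, Tensor):
            self.bias = Tensor(self.bias, requires_grad=True)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture settings.

    The default is the desk-scale preset (3 scales, channels 16/32/64,
    spectral hidden width 16); :meth:`published_scale` restores the published
    width (two transformer layers, 8 heads, hidden 512).
    """

    n_scales: int = 3
    channels: tuple[int, ...] = (16, 32, 64)
    fuse_channels: int = 16
    n_classes: int = 2  # segmentation label vocabulary K
    n_image_classes: int = 2
    spectral_encoder: str = "lstm"  # {"lstm", "transformer", "none"}
    spectral_hidden: int = 16
    transformer_layers: int = 2
    transformer_heads: int = 4
    kernel_size: int = 3
    stride: int = 2
    activation: str = "relu"
    dropout: float = 0.2
    proj_dim: int = 16
    attention_enabled: bool = True

    def __post_init__(self):
        if self.n_scales < 1:
            raise ConfigurationError("n_scales must be >= 1")
        if len(self.channels) != self.n_scales:
            raise ConfigurationError("need one channel count per scale")
        if self.n_classes < 2:
            raise ConfigurationError("K must be >= 2")
        if not (0 <= self.dropout < 1):
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.spectral_encoder not in ("lstm", "transformer", "none"):
            raise ConfigurationError(
                f"unknown spectral encoder {self.spectral_encoder!r}"
            )
        if self.spectral_encoder == "transformer" and (
            self.spectral_hidden % self.transformer_heads != 0
        ):
            raise ConfigurationError("spectral_hidden must divide into heads")

    @classmethod
    def published_scale(cls, **kw) -> "NetworkConfig":
        """The published transformer width: 2 layers, 8 heads, hidden 512."""
        kw.setdefault("spectral_encoder", "transformer")
        kw.setdefault("spectral_hidden", 512)
        kw.setdefault("transformer_layers", 2)
        kw.setdefault("transformer_heads", 8)
        return cls(**kw)


# -- helpers -------------------------------------------------------------------

def _as_batch(x) -> tuple[Tensor, bool]:
    """Coerce (H,W,C) or (N,H,W,C) input (array/Tensor/SpectralImage) to 4-D."""
    if isinstance(x, SpectralImage):
        x = x.data
    t = ad.as_tensor(x)
    if t.ndim == 3:
        return t.reshape((1,) + t.shape), True
    if t.ndim == 4:
        return t, False
    raise ShapeError(f"expected (H, W, C) or (N, H, W, C), got ndim={t.ndim}")


def _activate(t: Tensor, name: str) -> Tensor:
    return ad.relu(t) if name == "relu" else ad.leaky_relu(t)


def _interp_matrix(out_n: int, in_n: int) -> np.ndarray:
    """Row-stochastic 1-D linear interpolation matrix (corner-aligned)."""
    m = np.zeros((out_n, in_n))
    if in_n == 1:
        m[:, 0] = 1.0
        return m
    pos = np.linspace(0.0, in_n - 1, out_n)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, in_n - 1)
    frac = pos - lo
    m[np.arange(out_n), lo] += 1.0 - frac
    m[np.arange(out_n), hi] += frac
    return m


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Corner-aligned bilinear resampling of (N, H, W, C) features."""
    n, h, w, c = x.shape
    oh, ow = out_hw
    if (h, w) == (oh, ow):
        return x
    a_r = Tensor(_interp_matrix(oh, h))
    a_c = Tensor(_interp_matrix(ow, w))
    xt = x.transpose(0, 3, 1, 2)  # (N, C, H, W)
    yt = (a_r @ xt) @ a_c.transpose(1, 0)
    return yt.transpose(0, 2, 3, 1)


# -- spec operations -----------------------------------------------------------

def encode_level(f_prev, params: ConvLevelParams, stride: int = 1):
    """One convolutional encoding level: sigma(W * F + b)."""
    x, squeeze = _as_batch(f_prev)
    if x.shape[-1] != params.weight.shape[2]:
        raise ShapeError(
            f"input has {x.shape[-1]} channels, kernel expects {params.weight.shape[2]}"
        )
    out = _activate(ad.conv2d(x, params.weight, stride=stride) + params.bias,
                    params.activation)
    return out.reshape(out.shape[1:]) if squeeze else out


def build_pyramid(img, config: NetworkConfig, params: list[ConvLevelParams],
                  gate_logits: Tensor | None = None) -> FeaturePyramid:
    """Run the stride schedule: level 1 full-resolution, then /stride each."""
    if config.n_scales < 1 or len(params) == 0:
        raise ConfigurationError("pyramid needs at least one level of parameters")
    if len(params) != config.n_scales:
        raise ConfigurationError(
            f"got {len(params)} level params for {config.n_scales} scales"
        )
    x, _ = _as_batch(img)
    if min(x.shape[1], x.shape[2]) < config.stride ** (config.n_scales - 1):
        raise ShapeError("image smaller than the total downsampling factor")
    levels = []
    cur = x
    for m, p in enumerate(params):
        cur = encode_level(cur, p, stride=1 if m == 0 else config.stride)
        levels.append(cur)
    if gate_logits is None:
        gate_logits = Tensor(np.zeros(len(levels)), requires_grad=True)
    return FeaturePyramid(levels=levels, gate_logits=gate_logits)


def gated_fuse(pyr: FeaturePyramid) -> Tensor:
    """Softmax-gated sum of pyramid levels on the finest grid.

    Levels must share a channel width (project first if they do not); the
    computed softmax weights are stored on the pyramid (``alpha``).
    """
    levels = [l if isinstance(l, Tensor) else ad.as_tensor(l) for l in pyr.levels]
    if len(levels) == 1:
        pyr.alpha = np.array([1.0])
        pyr.fused = levels[0]
        return levels[0]
    widths = {l.shape[-1] for l in levels}
    if len(widths) != 1:
        raise ShapeError(f"levels must share a channel width to fuse, got {widths}")
    target = levels[0].shape[1:3]
    alpha = ad.softmax(pyr.gate_logits, axis=0)
    fused = None
    for m, level in enumerate(levels):
        up = bilinear_resize(level, target)
        term = alpha[(m,)] * up
        fused = term if fused is None else fused + term
    pyr.alpha = alpha.data.copy()
    pyr.fused = fused
    return fused


def attention_aggregate(f, att: AttentionState) -> Tensor:
    """A = sigmoid(W_A * F + b_A); F_att = A ⊙ F (element-wise)."""
    x, squeeze = _as_batch(f)
    if x.shape[-1] != att.weight.shape[2]:
        raise ShapeError(
            f"feature width {x.shape[-1]} does not match attention kernel "
            f"({att.weight.shape[2]})"
        )
    a = ad.sigmoid(ad.conv2d(x, att.weight, stride=1) + att.bias)
    f_att = a * x
    att.attention_map = a.data[..., 0].copy() if squeeze and a.shape[0] == 1 else (
        a.data[..., 0].copy()
    )
    att.f_att = f_att
    return f_att.reshape(f_att.shape[1:]) if squeeze else f_att


def encode_spectral_sequence(img, config: NetworkConfig, params: dict | None = None):
    """Per-pixel band-sequence features from the configured sequence model.

    ``none`` bypasses (returns the input features unchanged); ``lstm`` runs a
    bidirectional LSTM over the C bands of each pixel and returns the
    concatenated final hidden states; ``transformer`` embeds each band with a
    learned position code, applies the encoder stack and mean-pools over
    bands.
    """
    x, squeeze = _as_batch(img)
    if config.spectral_encoder == "none":
        return x.reshape(x.shape[1:]) if squeeze else x
    c = x.shape[-1]
    if c < 2:
        raise ConfigurationError(
            "spectral sequence encoding needs C >= 2 bands; set the encoder to 'none'"
        )
    if params is None:
        params = init_spectral_params(config, c, np.random.default_rng(0))
    if config.spectral_encoder == "lstm":
        out = _bilstm_over_bands(x, params, config.spectral_hidden)
    else:
        out = _transformer_over_bands(x, params, config)
    return out.reshape(out.shape[1:]) if squeeze else out


def predict(img, config: NetworkConfig, params: dict):
    """Forward pass returning (per-pixel probs (H,W,K), class probs (K,)).

    Probabilities are softmax-normalized; hard labels are obtained with
    ``argmax`` which breaks ties toward the smallest index.
    """
    model = SegmentationModel(config, params=params)
    x, _ = _as_batch(img)
    out = model.forward(x, train=False)
    seg = out["seg_probs"].data[0]
    cls = out["cls_probs"].data[0]
    if not (np.all(np.isfinite(seg)) and np.all(np.isfinite(cls))):
        raise NumericError("non-finite activations in the prediction head")
    return seg, cls


# -- parameter initialization --------------------------------------------------

def _he(rng, *shape):
    fan_in = int(np.prod(shape[:-1])) or 1
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def init_spectral_params(config: NetworkConfig, n_bands: int,
                         rng: np.random.Generator) -> dict[str, Tensor]:
    """Parameters for the configured spectral sequence encoder."""
    p: dict[str, Tensor] = {}
    h = config.spectral_hidden
    if config.spectral_encoder == "lstm":
        for d in ("fwd", "bwd"):
            p[f"lstm_{d}_wx"] = Tensor(_he(rng, 1, 4 * h), requires_grad=True)
            p[f"lstm_{d}_wh"] = Tensor(_he(rng, h, 4 * h) * 0.1, requires_grad=True)
            p[f"lstm_{d}_b"] = Tensor(np.zeros(4 * h), requires_grad=True)
    elif config.spectral_encoder == "transformer":
        p["emb_w"] = Tensor(_he(rng, 1, h), requires_grad=True)
        p["emb_b"] = Tensor(np.zeros(h), requires_grad=True)
        p["pos"] = Tensor(rng.normal(0, 0.02, (n_bands, h)), requires_grad=True)
        for layer in range(config.transformer_layers):
            for name in ("q", "k", "v", "o"):
                p[f"t{layer}_w{name}"] = Tensor(_he(rng, h, h) * 0.5,
                                                requires_grad=True)
            p[f"t{layer}_ff1"] = Tensor(_he(rng, h, 2 * h), requires_grad=True)
            p[f"t{layer}_ff1b"] = Tensor(np.zeros(2 * h), requires_grad=True)
            p[f"t{layer}_ff2"] = Tensor(_he(rng, 2 * h, h), requires_grad=True)
            p[f"t{layer}_ff2b"] = Tensor(np.zeros(h), requires_grad=True)
            for ln in ("ln1", "ln2"):
                p[f"t{layer}_{ln}_g"] = Tensor(np.ones(h), requires_grad=True)
                p[f"t{layer}_{ln}_b"] = Tensor(np.zeros(h), requires_grad=True)
    return p


def _bilstm_over_bands(x: Tensor, p: dict, hidden: int) -> Tensor:
    n, h, w, c = x.shape
    seq = x.reshape(n * h * w, c)
    outs = []
    for d, order in (("fwd", range(c)), ("bwd", range(c - 1, -1, -1))):
        wx, wh, b = p[f"lstm_{d}_wx"], p[f"lstm_{d}_wh"], p[f"lstm_{d}_b"]
        hs = ad.as_tensor(np.zeros((n * h * w, hidden)))
        cs = ad.as_tensor(np.zeros((n * h * w, hidden)))
        for t in order:
            xt = seq[(slice(None), slice(t, t + 1))]  # (P, 1)
            gates = xt @ wx + hs @ wh + b
            i = ad.sigmoid(gates[(slice(None), slice(0, hidden))])
            f = ad.sigmoid(gates[(slice(None), slice(hidden, 2 * hidden))])
            o = ad.sigmoid(gates[(slice(None), slice(2 * hidden, 3 * hidden))])
            g = ad.tanh(gates[(slice(None), slice(3 * hidden, 4 * hidden))])
            cs = f * cs + i * g
            hs = o * ad.tanh(cs)
        outs.append(hs)
    out = ad.concat(outs, axis=1)
    return out.reshape(n, h, w, 2 * hidden)


def _layer_norm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) * ((var + 1e-5) ** -0.5) * g + b


def _transformer_over_bands(x: Tensor, p: dict, config: NetworkConfig) -> Tensor:
    n, h, w, c = x.shape
    d = config.spectral_hidden
    heads = config.transformer_heads
    dk = d // heads
    seq = x.reshape(n * h * w, c, 1)
    e = seq @ p["emb_w"] + p["emb_b"] + p["pos"]  # (P, C, d)
    for layer in range(config.transformer_layers):
        q = e @ p[f"t{layer}_wq"]
        k = e @ p[f"t{layer}_wk"]
        v = e @ p[f"t{layer}_wv"]
        parts = []
        for head in range(heads):
            sl = (slice(None), slice(None), slice(head * dk, (head + 1) * dk))
            qs, ks, vs = q[sl], k[sl], v[sl]
            scores = (qs @ ks.transpose(0, 2, 1)) * (dk**-0.5)
            attn = ad.softmax(scores, axis=-1)
            parts.append(attn @ vs)
        att_out = ad.concat(parts, axis=2) @ p[f"t{layer}_wo"]
        e = _layer_norm(e + att_out, p[f"t{layer}_ln1_g"], p[f"t{layer}_ln1_b"])
        ff = ad.relu(e @ p[f"t{layer}_ff1"] + p[f"t{layer}_ff1b"])
        ff = ff @ p[f"t{layer}_ff2"] + p[f"t{layer}_ff2b"]
        e = _layer_norm(e + ff, p[f"t{layer}_ln2_g"], p[f"t{layer}_ln2_b"])
    pooled = e.mean(axis=1)  # (P, d)
    return pooled.reshape(n, h, w, d)


# -- the assembled model -------------------------------------------------------

class SegmentationModel:
    """Parameter container plus forward pass for the full network."""

    def __init__(self, config: NetworkConfig, n_bands: int | None = None,
                 params: dict[str, Tensor] | None = None,
                 seed: int = 0):
        self.config = config
        if params is not None:
            self.params = params
            self.n_bands = int(params["meta_n_bands"].data) if "meta_n_bands" in (
                params
            ) else n_bands
        else:
            if n_bands is None:
                raise ConfigurationError("n_bands is required to initialize")
            self.n_bands = n_bands
            self.params = self._init_params(np.random.default_rng(seed))

    # channel width entering the attention stage
    @property
    def _comb_channels(self) -> int:
        cfg = self.config
        spec_c = {"lstm": 2 * cfg.spectral_hidden,
                  "transformer": cfg.spectral_hidden,
                  "none": self.n_bands}[cfg.spectral_encoder]
        return cfg.fuse_channels + spec_c

    def _init_params(self, rng: np.random.Generator) -> dict[str, Tensor]:
        cfg = self.config
        k = cfg.kernel_size
        p: dict[str, Tensor] = {"meta_n_bands": Tensor(float(self.n_bands))}
        cin = self.n_bands
        for m, cout in enumerate(cfg.channels):
            p[f"conv{m}_w"] = Tensor(_he(rng, k, k, cin, cout), requires_grad=True)
            p[f"conv{m}_b"] = Tensor(np.zeros(cout), requires_grad=True)
            cin = cout
        for m, cout in enumerate(cfg.channels):
            p[f"proj{m}_w"] = Tensor(_he(rng, 1, 1, cout, cfg.fuse_channels),
                                     requires_grad=True)
            p[f"proj{m}_b"] = Tensor(np.zeros(cfg.fuse_channels), requires_grad=True)
        p["gate_logits"] = Tensor(np.zeros(cfg.n_scales), requires_grad=True)
        p.update(init_spectral_params(cfg, self.n_bands, rng))
        comb = self._comb_channels
        p["att_w"] = Tensor(_he(rng, 1, 1, comb, 1), requires_grad=True)
        p["att_b"] = Tensor(np.zeros(1), requires_grad=True)
        p["seg_w"] = Tensor(_he(rng, 1, 1, comb, cfg.n_classes), requires_grad=True)
        p["seg_b"] = Tensor(np.zeros(cfg.n_classes), requires_grad=True)
        p["cls_w"] = Tensor(_he(rng, comb, cfg.n_image_classes), requires_grad=True)
        p["cls_b"] = Tensor(np.zeros(cfg.n_image_classes), requires_grad=True)
        p["proj_head_w"] = Tensor(_he(rng, comb, cfg.proj_dim), requires_grad=True)
        p["proj_head_b"] = Tensor(np.zeros(cfg.proj_dim), requires_grad=True)
        return p

    def trainable(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if k != "meta_n_bands"}

    def conv_levels(self) -> list[ConvLevelParams]:
        return [
            ConvLevelParams(self.params[f"conv{m}_w"], self.params[f"conv{m}_b"],
                            self.config.activation)
            for m in range(self.config.n_scales)
        ]

    def forward(self, x, train: bool = False,
                rng: np.random.Generator | None = None) -> dict:
        cfg = self.config
        x, _ = _as_batch(x)
        pyr = build_pyramid(x, cfg, self.conv_levels(),
                            gate_logits=self.params["gate_logits"])
        projected = []
        for m, level in enumerate(pyr.levels):
            proj = ad.conv2d(level, self.params[f"proj{m}_w"]) + self.params[
                f"proj{m}_b"
            ]
            projected.append(proj)
        proj_pyr = FeaturePyramid(levels=projected,
                                  gate_logits=self.params["gate_logits"])
        fused = gated_fuse(proj_pyr)

        spec = encode_spectral_sequence(x, cfg, self.params)
        comb = ad.concat([fused, spec], axis=3)

        if train and cfg.dropout > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            keep = (rng.random(comb.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            comb = comb * ad.as_tensor(keep)

        if cfg.attention_enabled:
            att = AttentionState(self.params["att_w"], self.params["att_b"])
            f_att = attention_aggregate(comb, att)
        else:
            att = None
            f_att = comb

        seg_logits = ad.conv2d(f_att, self.params["seg_w"]) + self.params["seg_b"]
        seg_probs = ad.softmax(seg_logits, axis=3)
        pooled = f_att.mean(axis=(1, 2))  # (N, comb)
        cls_logits = pooled @ self.params["cls_w"] + self.params["cls_b"]
        cls_probs = ad.softmax(cls_logits, axis=1)
        proj = pooled @ self.params["proj_head_w"] + self.params["proj_head_b"]
        return {
            "pyramid": proj_pyr,
            "alpha": proj_pyr.alpha,
            "fused": fused,
            "attention": att,
            "f_att": f_att,
            "seg_probs": seg_probs,
            "cls_probs": cls_probs,
            "pooled": pooled,
            "proj": proj,
        }
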