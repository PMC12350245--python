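"""Objective terms: supervised, adversarial, contrastive, knowledge, calibration.

Every term accepts either plain NumPy arrays (returning a ``float``) or
:class:`~specseg.autodiff.Tensor` inputs (returning a ``Tensor`` wired into
the autodiff graph), so the same definitions serve the public API, the test
oracles and the training loop.

Conventions
-----------
* All probabilities entering a logarithm are clamped to [1e-7, 1 - 1e-7].
* Squared Euclidean distance is used for the domain-alignment term (the
  everywhere-differentiable reading of the feature-distance penalty).
* The discriminator objective is the quantity the discriminator *maximizes*
  (mean log D on source plus mean log(1 - D) on target); it is <= 0 by
  construction.  All other terms are >= 0.
* The total objective is
  ``seg + l_cls*cls + l_da*da + l_cl*cl + l_kr*kr + l_uc*uc``; the
  classification term is retained alongside the four auxiliary terms so the
  supervised composite and the full objective are honored simultaneously.
  The discriminator term enters training through the separate adversarial
  min-max coupling, not the total.
* The uncertainty-calibration term is a Brier-style surrogate — the mean
  squared gap between per-pixel confidence (max probability) and per-pixel
  correctness — chosen because it is bounded, differentiable and needs only
  quantities the model already produces.  This functional form is this
  package's interpretation; it is not uniquely fixed by the framework.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import (
    DataError,
    DomainError,
    NumericError,
    ShapeError,
    ValidationError,
)
from .phantoms import AnatomicalPriorSet

__all__ = [
    "LossWeights",
    "DomainBatch",
    "EmbeddingBatch",
    "LossReport",
    "seg_loss",
    "cls_loss",
    "composite_supervised",
    "domain_alignment_loss",
    "discriminator_loss",
    "adversarial_objective",
    "cosine_sim",
    "contrastive_loss",
    "soft_centroid",
    "soft_centroids_from_probs",
    "knowledge_reg_loss",
    "uncertainty_loss",
    "total_loss",
]

_EPS = 1e-7

#: incremented whenever discriminator probabilities had to be clamped away
#: from exactly 0 or 1
CLAMP_COUNTER = {"count": 0}


@dataclass(frozen=True)
class LossWeights:
    """Coefficients of the composite objective.

    Defaults are the published operating point: lambda_da=1.0, lambda_cl=0.5,
    lambda_kr=1.0, lambda_uc=0.2, tau=0.07.  lambda_cls and lambda_adv have no
    published value; lambda_cls defaults to 1.0, and lambda_adv to 0.1 because
    the saturating min-max coupling oscillates at small batch sizes when the
    adversarial gradient rivals the alignment gradient (see the methods note).
    """

    lambda_cls: float = 1.0
    lambda_adv: float = 0.1
    lambda_da: float = 1.0
    lambda_cl: float = 0.5
    lambda_kr: float = 1.0
    lambda_uc: float = 0.2
    tau: float = 0.07

    def __post_init__(self):
        for name in ("lambda_cls", "lambda_adv", "lambda_da", "lambda_cl",
                     "lambda_kr", "lambda_uc"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.tau <= 0:
            raise ValidationError("tau must be > 0")


@dataclass
class DomainBatch:
    """Feature batches from the source and target domains."""

    source_features: np.ndarray | Tensor
    target_features: np.ndarray | Tensor

    def __post_init__(self):
        fs, ft = _data(self.source_features), _data(self.target_features)
        if fs.ndim != 2 or ft.ndim != 2:
            raise ShapeError("features must be (N, D) matrices")
        if fs.shape[0] < 1 or ft.shape[0] < 1:
            raise ValidationError("both domains need at least one feature vector")
        if fs.shape[1] != ft.shape[1]:
            raise ShapeError("source and target feature dimensionality differ")


@dataclass
class EmbeddingBatch:
    """Two augmented views of the same batch of images."""

    view1: np.ndarray | Tensor
    view2: np.ndarray | Tensor

    def __post_init__(self):
        v1, v2 = _data(self.view1), _data(self.view2)
        if v1.shape != v2.shape or v1.ndim != 2:
            raise ShapeError("views must be equal-shape (B, D) matrices")
        if v1.shape[0] < 2:
            raise ValidationError("contrastive batches need B >= 2")
        if np.any(np.linalg.norm(v1, axis=1) == 0) or np.any(
            np.linalg.norm(v2, axis=1) == 0
        ):
            raise DomainError("zero embedding vector in contrastive batch")


@dataclass
class LossReport:
    """All objective components plus their weighted total."""

    seg: float
    cls: float
    da: float
    disc: float
    cl: float
    kr: float
    uc: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("seg", "cls", "da", "disc", "cl", "kr", "uc", "total")}


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _is_tensor_input(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _finish(t: Tensor, tensor_mode: bool):
    return t if tensor_mode else float(t.data)


# -- supervised ---------------------------------------------------------------

def seg_loss(prob_map, mask):
    """Mean per-pixel cross-entropy -log p(true label).

    ``prob_map``: (H, W, K) or (N, H, W, K), normalized; ``mask``: matching
    integer labels.
    """
    tensor_mode = _is_tensor_input(prob_map)
    p = ad.as_tensor(prob_map)
    mask = np.asarray(_data(mask), dtype=np.int64)
    if p.data.shape[:-1] != mask.shape:
        raise ShapeError(
            f"prob_map spatial shape {p.data.shape[:-1]} != mask shape {mask.shape}"
        )
    idx = tuple(np.indices(mask.shape)) + (mask,)
    picked = ad.clip(p, _EPS, 1.0 - _EPS)[idx]
    return _finish(-(ad.log(picked).mean()), tensor_mode)


def cls_loss(class_probs, label):
    """Image-level cross-entropy; accepts a single vector or a (N, K) batch."""
    tensor_mode = _is_tensor_input(class_probs)
    p = ad.as_tensor(class_probs)
    label = np.asarray(label, dtype=np.int64)
    if p.data.ndim == 1:
        picked = ad.clip(p, _EPS, 1.0 - _EPS)[(int(label),)]
    else:
        picked = ad.clip(p, _EPS, 1.0 - _EPS)[(np.arange(p.shape[0]), label)]
    return _finish(-(ad.log(picked).mean()), tensor_mode)


def composite_supervised(seg, cls, weights: LossWeights):
    """Supervised composite ``seg + lambda_cls * cls``."""
    tensor_mode = _is_tensor_input(seg, cls)
    out = ad.as_tensor(seg) + weights.lambda_cls * ad.as_tensor(cls)
    return _finish(out, tensor_mode)


# -- domain adaptation --------------------------------------------------------

def domain_alignment_loss(batch: DomainBatch):
    """Mean squared Euclidean distance over all source/target feature pairs.

    Computed in closed form: mean ||fs||^2 + mean ||ft||^2 - 2 mu_s . mu_t,
    identical to the nested double sum.
    """
    tensor_mode = _is_tensor_input(batch.source_features, batch.target_features)
    fs = ad.as_tensor(batch.source_features)
    ft = ad.as_tensor(batch.target_features)
    out = (
        (fs**2).sum(axis=1).mean()
        + (ft**2).sum(axis=1).mean()
        - 2.0 * (fs.mean(axis=0) @ ft.mean(axis=0))
    )
    return _finish(out, tensor_mode)


def discriminator_loss(d_source, d_target):
    """Mean log D on source plus mean log(1 - D) on target; <= 0.

    Probabilities exactly at 0 or 1 are clamped to [1e-7, 1 - 1e-7] and the
    module-level ``CLAMP_COUNTER`` is incremented.
    """
    tensor_mode = _is_tensor_input(d_source, d_target)
    ds, dt = ad.as_tensor(d_source), ad.as_tensor(d_target)
    for d in (ds, dt):
        if np.any(d.data < 0) or np.any(d.data > 1):
            raise ValidationError("discriminator outputs must lie in [0, 1]")
    n_clamped = int(np.sum((ds.data <= 0) | (ds.data >= 1))) + int(
        np.sum((dt.data <= 0) | (dt.data >= 1))
    )
    if n_clamped:
        CLAMP_COUNTER["count"] += n_clamped
        warnings.warn(f"clamped {n_clamped} discriminator probabilities away from 0/1",
                      stacklevel=2)
    out = ad.log(ad.clip(ds, _EPS, 1.0 - _EPS)).mean() + ad.log(
        1.0 - ad.clip(dt, _EPS, 1.0 - _EPS)
    ).mean()
    return _finish(out, tensor_mode)


def adversarial_objective(da, disc, weights: LossWeights):
    """Value of the min-max coupling ``L_DA + lambda_adv * L_disc``.

    Training contract: the discriminator ascends ``disc``; the encoder
    descends this combined objective (alternating updates or gradient
    reversal).
    """
    tensor_mode = _is_tensor_input(da, disc)
    out = ad.as_tensor(da) + weights.lambda_adv * ad.as_tensor(disc)
    return _finish(out, tensor_mode)


# -- contrastive --------------------------------------------------------------

def cosine_sim(u, v):
    """Cosine similarity u.v / (||u|| ||v||)."""
    tensor_mode = _is_tensor_input(u, v)
    u, v = ad.as_tensor(u), ad.as_tensor(v)
    nu = float(np.linalg.norm(u.data))
    nv = float(np.linalg.norm(v.data))
    if nu == 0 or nv == 0:
        raise DomainError("cosine similarity undefined for a zero vector")
    out = (u @ v) * (((u**2).sum() ** 0.5 * (v**2).sum() ** 0.5) ** -1.0)
    return _finish(out, tensor_mode)


def _row_normalize(v: Tensor) -> Tensor:
    norms = ((v**2).sum(axis=1, keepdims=True)) ** 0.5
    return v / norms


def contrastive_loss(batch: EmbeddingBatch, tau: float = 0.07):
    """Normalized temperature-scaled cross-entropy over view pairs.

    For each anchor i in view 1 the positive is its own view-2 embedding and
    the denominator runs over all B view-2 embeddings (exactly the printed
    form — same-view negatives are not included).  Returns the *sum* over the
    batch, which is >= 0.
    """
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    tensor_mode = _is_tensor_input(batch.view1, batch.view2)
    v1 = _row_normalize(ad.as_tensor(batch.view1))
    v2 = _row_normalize(ad.as_tensor(batch.view2))
    b = v1.shape[0]
    sims = (v1 @ v2.transpose(1, 0)) * (1.0 / tau)
    logp = ad.log_softmax(sims, axis=1)
    diag = logp[(np.arange(b), np.arange(b))]
    return _finish(-(diag.sum()), tensor_mode)


# -- knowledge regularization -------------------------------------------------

def soft_centroid(prob_channel):
    """Probability-weighted centre of mass (row, col) of one structure map."""
    tensor_mode = _is_tensor_input(prob_channel)
    p = ad.as_tensor(prob_channel)
    if p.data.ndim != 2:
        raise ShapeError("structure probability map must be 2-D")
    mass = float(p.data.sum())
    if mass <= 0:
        raise DataError("structure map carries no probability mass")
    h, w = p.data.shape
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    total = p.sum()
    r = (p * rows).sum() / total
    c = (p * cols).sum() / total
    return (r, c) if tensor_mode else (float(r.data), float(c.data))


def soft_centroids_from_probs(prob_map, structure_ids) -> dict:
    """Soft centroids of each structure's predicted map.

    ``prob_map`` is (H, W, K) with structure id ``s`` living in channel
    ``s + 1`` (channel 0 is background).
    """
    out = {}
    for sid in structure_ids:
        channel = prob_map[:, :, sid + 1] if isinstance(prob_map, Tensor) else (
            np.asarray(prob_map)[:, :, sid + 1]
        )
        try:
            out[sid] = soft_centroid(channel)
        except DataError as exc:
            raise DataError(f"structure {sid}: {exc}") from exc
    return out


def knowledge_reg_loss(centroids: dict, prior: AnatomicalPriorSet):
    """Sum of squared gaps between predicted and prior pairwise distances.

    ``centroids`` maps structure id -> (row, col), where the coordinates may
    be floats or Tensors.  Zero iff every predicted distance matches its
    prior; invariant to a global translation of all centroids.
    """
    tensor_mode = any(
        _is_tensor_input(*pair) for pair in centroids.values()
    )
    total = ad.as_tensor(0.0)
    for i, j, d_prior in prior.pairs:
        for sid in (i, j):
            if sid not in centroids:
                raise DataError(f"no predicted centroid for structure {sid}")
        ri, ci = (ad.as_tensor(v) for v in centroids[i])
        rj, cj = (ad.as_tensor(v) for v in centroids[j])
        d = ((ri - rj) ** 2 + (ci - cj) ** 2 + 1e-12) ** 0.5
        total = total + (d - d_prior) ** 2
    return _finish(total, tensor_mode)


# -- uncertainty calibration ---------------------------------------------------

def uncertainty_loss(prob_map, mask):
    """Brier-style calibration surrogate in [0, 1].

    Mean squared difference between per-pixel confidence (the maximum class
    probability) and the 0/1 correctness of the argmax prediction.
    """
    tensor_mode = _is_tensor_input(prob_map)
    p = ad.as_tensor(prob_map)
    mask = np.asarray(_data(mask), dtype=np.int64)
    if p.data.shape[:-1] != mask.shape:
        raise ShapeError("prob_map and mask shapes are incompatible")
    pred = np.argmax(p.data, axis=-1)
    correct = (pred == mask).astype(np.float64)
    idx = tuple(np.indices(mask.shape)) + (pred,)
    conf = p[idx]
    out = ((conf - correct) ** 2).mean()
    return _finish(out, tensor_mode)


# -- composition ---------------------------------------------------------------

def total_loss(seg, cls, da, disc, cl, kr, uc, weights: LossWeights) -> LossReport:
    """Compose the full objective and return a :class:`LossReport`.

    ``total = seg + l_cls*cls + l_da*da + l_cl*cl + l_kr*kr + l_uc*uc``; the
    discriminator value is recorded but enters only the adversarial coupling.
    """
    parts = {"seg": seg, "cls": cls, "da": da, "disc": disc, "cl": cl,
             "kr": kr, "uc": uc}
    vals = {}
    for name, v in parts.items():
        val = float(_data(v)) if not np.isscalar(v) else float(v)
        if not np.isfinite(val):
            raise NumericError(f"loss term {name!r} is non-finite ({val})")
        vals[name] = val
    total = (
        vals["seg"]
        + weights.lambda_cls * vals["cls"]
        + weights.lambda_da * vals["da"]
        + weights.lambda_cl * vals["cl"]
        + weights.lambda_kr * vals["kr"]
        + weights.lambda_uc * vals["uc"]
    )
    return LossReport(total=total, **vals)
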