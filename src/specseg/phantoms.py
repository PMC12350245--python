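"""Synthetic multispectral lesion phantoms with known ground truth.

Every other module in the package is exercised against phantoms generated
here: small H x W x C rasters containing one lesion disc (whose spectral
signature encodes its class), optional fixed "anatomy" reference discs used
by the knowledge-regularization prior, and a two-domain acquisition shift.

Model of the data
-----------------
* Background pixels carry a flat spectrum at a low baseline level.
* Lesion pixels of class ``c`` carry a Gaussian bump over the band index,
  centred at ``signature_centers[c]`` with width ``signature_width`` — band
  order is therefore meaningful, which is what motivates treating spectra as
  ordered sequences.
* Anatomy structures (ids 1..n_structures-1) sit at deterministic positions
  on a circle around the image centre and carry their own spectral bumps.
* i.i.d. Gaussian noise (``noise_sd``) is added to every band.
* Target-domain phantoms get a per-band affine shift (``domain_gain`` /
  ``domain_offset``) applied after signature synthesis and noise — the
  simplest shift the domain-alignment loss can provably reduce.

Seeding
-------
A single master seed is split into named substreams through NumPy's
``SeedSequence(seed, spawn_key=(STREAM_ID, index))`` counter scheme with
stream ids ``geometry=0``, ``spectra=1``, ``noise=2``; adding a stream never
perturbs the others, and the same (config, class, domain, index) always
reproduces the same phantom bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError, DomainError
from .spectral_io import SpectralImage

__all__ = [
    "PhantomConfig",
    "SpectralPhantom",
    "AnatomicalPriorSet",
    "generate_phantom",
    "generate_domain_pair",
    "derive_prior_set",
]

_STREAMS = {"geometry": 0, "spectra": 1, "noise": 2}
_BACKGROUND_LEVEL = 0.1
_LESION_AMPLITUDE = 1.0
_ANATOMY_AMPLITUDE = 0.7
# index offset separating target-domain substreams from source-domain ones
_TARGET_INDEX_OFFSET = 1_000_000


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, spectra, noise and domain-shift settings for one phantom family."""

    height: int = 32
    width: int = 32
    n_bands: int = 8
    n_structures: int = 1
    lesion_radius_range: tuple[float, float] = (4.0, 6.0)
    signature_centers: tuple[float, ...] = (2.0, 5.0)
    signature_width: float = 1.5
    noise_sd: float = 0.1
    domain_gain: float = 1.0
    domain_offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ConfigurationError("height and width must be >= 8")
        if self.n_bands < 2:
            raise ConfigurationError("n_bands must be >= 2")
        if self.n_structures < 1:
            raise ConfigurationError("n_structures must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ConfigurationError("lesion_radius_range must satisfy 0 < min <= max")
        if hi >= min(self.height, self.width) / 2:
            raise ConfigurationError("lesion radius too large for the image")
        if not self.signature_centers:
            raise ConfigurationError("at least one signature class is required")

    @property
    def n_classes(self) -> int:
        """Number of lesion signature classes."""
        return len(self.signature_centers)

    @property
    def n_seg_labels(self) -> int:
        """Segmentation label vocabulary: background + every structure id."""
        return self.n_structures + 1


@dataclass
class SpectralPhantom:
    """A generated phantom: image, mask, class label, domain and centroids."""

    image: SpectralImage
    mask: np.ndarray
    class_label: int
    domain: str
    structure_centroids: list[tuple[float, float]]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=np.int64)
        if self.mask.shape != self.image.data.shape[:2]:
            raise DataError("mask shape does not match image spatial shape")

    def training_mask(self) -> np.ndarray | None:
        """Mask exposed to training code: withheld for target-domain phantoms."""
        return None if self.domain == "target" else self.mask


@dataclass(frozen=True)
class AnatomicalPriorSet:
    """Unordered pairs of structure ids with expected centroid distances."""

    pairs: tuple[tuple[int, int, float], ...] = field(default_factory=tuple)

    def __post_init__(self):
        seen = set()
        for i, j, d in self.pairs:
            if i == j:
                raise DataError(f"prior pair ({i}, {j}) is degenerate")
            if d < 0:
                raise DataError(f"prior distance for ({i}, {j}) is negative")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise DataError(f"duplicate prior pair {key}")
            seen.add(key)

    def as_dict(self) -> dict[tuple[int, int], float]:
        return {(min(i, j), max(i, j)): d for i, j, d in self.pairs}


def _rng(config: PhantomConfig, stream: str, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream], index))
    return np.random.default_rng(ss)


def _anatomy_layout(config: PhantomConfig) -> list[tuple[float, float, float]]:
    """Deterministic (row, col, radius) for anatomy structures 1..S-1."""
    s = config.n_structures - 1
    if s == 0:
        return []
    cy, cx = (config.height - 1) / 2.0, (config.width - 1) / 2.0
    ring = min(config.height, config.width) / 3.0
    radius = max(2.0, min(config.height, config.width) / 16.0)
    out = []
    for k in range(s):
        ang = 2.0 * np.pi * k / s
        out.append((cy + ring * np.sin(ang), cx + ring * np.cos(ang), radius))
    return out


def _disc_mask(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _signature(config: PhantomConfig, center: float, amplitude: float) -> np.ndarray:
    bands = np.arange(config.n_bands, dtype=np.float64)
    return _BACKGROUND_LEVEL + amplitude * np.exp(
        -((bands - center) ** 2) / (2.0 * config.signature_width**2)
    )


def generate_phantom(
    config: PhantomConfig,
    class_label: int,
    domain: str = "source",
    index: int = 0,
) -> SpectralPhantom:
    """Generate one phantom.

    ``index`` selects independent substreams so that a family of phantoms can
    be drawn from one config; index 0 reproduces the single-phantom case.
    """
    if domain not in ("source", "target"):
        raise DomainError(f"domain must be 'source' or 'target', got {domain!r}")
    if not (0 <= class_label < config.n_classes):
        raise DomainError(
            f"class_label {class_label} out of range for {config.n_classes} classes"
        )
    h, w = config.height, config.width
    geo = _rng(config, "geometry", index)
    anatomy = _anatomy_layout(config)

    r_lo, r_hi = config.lesion_radius_range
    margin = r_hi + 1.0
    lesion_r = geo.uniform(r_lo, r_hi)
    # rejection-sample the lesion centre so it clears the anatomy discs
    for _ in range(100):
        cy = geo.uniform(margin, h - 1 - margin)
        cx = geo.uniform(margin, w - 1 - margin)
        if all(
            np.hypot(cy - ay, cx - ax) > lesion_r + ar + 1.0 for ay, ax, ar in anatomy
        ):
            break

    mask = np.zeros((h, w), dtype=np.int64)
    mask[_disc_mask(h, w, cy, cx, lesion_r)] = 1
    centroids = [(float(cy), float(cx))]
    for sid, (ay, ax, ar) in enumerate(anatomy, start=2):
        mask[_disc_mask(h, w, ay, ax, ar)] = sid  # anatomy overwrites overlap
        centroids.append((float(ay), float(ax)))

    data = np.empty((h, w, config.n_bands), dtype=np.float64)
    data[:] = _BACKGROUND_LEVEL
    data[mask == 1] = _signature(config, config.signature_centers[class_label],
                                 _LESION_AMPLITUDE)
    for sid in range(2, config.n_structures + 1):
        # anatomy bumps at evenly spaced band positions, distinct per structure
        center = (config.n_bands - 1) * (sid - 1) / config.n_structures
        data[mask == sid] = _signature(config, center, _ANATOMY_AMPLITUDE)

    if config.noise_sd > 0:
        noise = _rng(config, "noise", index).normal(0.0, config.noise_sd, data.shape)
        data = data + noise
    if domain == "target":
        data = config.domain_gain * data + config.domain_offset

    image = SpectralImage.from_array(
        data, provenance=f"phantom seed={config.seed} index={index} domain={domain}"
    )
    return SpectralPhantom(
        image=image,
        mask=mask,
        class_label=int(class_label),
        domain=domain,
        structure_centroids=centroids,
    )


def generate_domain_pair(
    config: PhantomConfig, n_source: int, n_target: int
) -> tuple[list[SpectralPhantom], list[SpectralPhantom]]:
    """Generate a fully labeled source cohort and a shifted target cohort.

    Target phantoms keep their masks internally (for evaluation) but expose
    ``training_mask() is None``.  Class labels cycle through the configured
    signature classes.
    """
    if n_source < 1 or n_target < 1:
        raise DomainError("n_source and n_target must both be >= 1")
    source = [
        generate_phantom(config, i % config.n_classes, "source", index=i)
        for i in range(n_source)
    ]
    target = [
        generate_phantom(
            config, j % config.n_classes, "target", index=_TARGET_INDEX_OFFSET + j
        )
        for j in range(n_target)
    ]
    return source, target


def derive_prior_set(phantoms: list[SpectralPhantom]) -> AnatomicalPriorSet:
    """Mean centroid distance per unordered structure pair across phantoms."""
    if not phantoms:
        raise DataError("need at least one phantom to derive a prior")
    n = len(phantoms[0].structure_centroids)
    ids = list(range(n))
    for p in phantoms:
        if len(p.structure_centroids) != n:
            missing = set(ids) ^ set(range(len(p.structure_centroids)))
            raise DataError(f"phantom is missing structure(s) {sorted(missing)}")
        for sid in ids:
            label = sid + 1  # structure id sid is stored as mask label sid+1
            if not np.any(p.mask == label):
                raise DataError(f"structure {sid} absent from a phantom mask")
    pairs = []
    for i, j in itertools.combinations(ids, 2):
        dists = [
            float(np.hypot(
                p.structure_centroids[i][0] - p.structure_centroids[j][0],
                p.structure_centroids[i][1] - p.structure_centroids[j][1],
            ))
            for p in phantoms
        ]
        pairs.append((i, j, float(np.mean(dists))))
    return AnatomicalPriorSet(pairs=tuple(pairs))
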