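"""Reading and writing spectral images, masks, manifests and prior tables.

Images are H x W x C rasters with the band axis last.  Two container formats
are supported: NIfTI-1 (``.nii`` / ``.nii.gz``, via nibabel) and multiband
TIFF (via tifffile).  Both round-trip losslessly at double precision (NIfTI)
and the written TIFF sample type (float64 for images, int32 for masks).

DICOM is deliberately not supported: convert to NIfTI first.  The NIfTI
affine is carried opaquely (written as identity, never interpreted).

Canonicalization: a 3-D raster read from disk is returned band-axis-last
regardless of on-disk layout.  The band axis is inferred as the axis of
smallest length; ties are resolved in favour of the last axis, so square
images with C < min(H, W) — the supported regime — are unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

__all__ = [
    "SpectralImage",
    "ManifestRecord",
    "DatasetManifest",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "load_manifest",
    "save_manifest",
    "load_prior_table",
    "save_prior_table",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")
_SPLITS = ("train", "val", "test")


@dataclass
class SpectralImage:
    """An H x W x C multiband raster with band ordering metadata."""

    data: np.ndarray
    band_order: list[str]
    spacing: tuple[float, float] | None = None
    provenance: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"expected 3-D (H, W, C) raster, got {self.data.ndim}-D")
        if self.data.shape[2] != len(self.band_order):
            raise ValidationError(
                f"band_order has {len(self.band_order)} entries for {self.data.shape[2]} bands"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("image contains non-finite values")

    @classmethod
    def from_array(cls, data: np.ndarray, provenance: str = "") -> "SpectralImage":
        data = np.asarray(data, dtype=np.float64)
        if data.ndim == 2:
            data = data[:, :, None]
        bands = [f"band_{i}" for i in range(data.shape[2])]
        return cls(data=data, band_order=bands, provenance=provenance)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


def _band_axis_last(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr[:, :, None]
    if arr.ndim != 3:
        raise FormatError(f"expected 2-D or 3-D raster on disk, got {arr.ndim}-D")
    sizes = arr.shape
    # smallest axis is the band axis; prefer the last axis on ties
    band_ax = int(np.argmin(sizes[::-1]))
    band_ax = arr.ndim - 1 - band_ax
    return np.moveaxis(arr, band_ax, -1)


def _dispatch(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_TIFF_SUFFIXES):
        return "tiff"
    raise FormatError(
        f"unsupported extension on {path}: expected .nii, .nii.gz, .tif or .tiff"
    )


def _read_array(path: Path) -> np.ndarray:
    kind = _dispatch(path)
    try:
        if kind == "nifti":
            arr = np.asarray(nib.load(str(path)).dataobj)
        else:
            arr = tifffile.imread(str(path))
    except FormatError:
        raise
    except Exception as exc:  # corrupt container
        raise OSError(f"failed to read {path}: {exc}") from exc
    return _band_axis_last(np.asarray(arr))


def read_image(path: str | Path) -> SpectralImage:
    """Read a NIfTI or multiband TIFF raster, band axis last."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    arr = _read_array(path).astype(np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{path} contains non-finite values")
    return SpectralImage.from_array(arr, provenance=str(path))


def write_image(img: SpectralImage, path: str | Path) -> Path:
    """Write a :class:`SpectralImage` losslessly (float64)."""
    path = Path(path)
    if not np.all(np.isfinite(img.data)):
        raise ValidationError("refusing to write non-finite image data")
    kind = _dispatch(path)
    data = img.data.astype(np.float64)
    if kind == "nifti":
        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    else:
        tifffile.imwrite(str(path), data, photometric="minisblack")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read an integer label raster; returns an (H, W) int array."""
    arr = _read_array(Path(path))
    if arr.shape[2] != 1:
        raise FormatError(f"mask at {path} has {arr.shape[2]} bands, expected 1")
    return np.rint(arr[:, :, 0]).astype(np.int64)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write an (H, W) integer label raster in the image container format."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got {mask.ndim}-D")
    path = Path(path)
    kind = _dispatch(path)
    if kind == "nifti":
        nib.save(nib.Nifti1Image(mask.astype(np.int32), affine=np.eye(4)), str(path))
    else:
        tifffile.imwrite(str(path), mask.astype(np.int32), photometric="minisblack")
    return path


# -- dataset manifests ---------------------------------------------------------

@dataclass
class ManifestRecord:
    image_path: str
    domain: str
    split: str
    mask_path: str | None = None
    class_label: int | None = None


@dataclass
class DatasetManifest:
    """Validated list of dataset records with disjoint train/val/test splits."""

    records: list[ManifestRecord] = field(default_factory=list)
    root: Path = field(default_factory=Path)

    def split(self, name: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.split == name]

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.root / p


def _validate_records(records: list[ManifestRecord], root: Path) -> None:
    if not records:
        raise ValidationError("manifest contains no records")
    seen: dict[str, str] = {}
    dangling: list[str] = []
    for r in records:
        if r.split not in _SPLITS:
            raise ValidationError(f"unknown split {r.split!r} for {r.image_path}")
        if r.domain not in ("source", "target"):
            raise ValidationError(f"unknown domain {r.domain!r} for {r.image_path}")
        prev = seen.get(r.image_path)
        if prev is not None and prev != r.split:
            raise ValidationError(
                f"{r.image_path} appears in both {prev!r} and {r.split!r} splits"
            )
        seen[r.image_path] = r.split
        for p in (r.image_path, r.mask_path):
            if p is not None:
                full = Path(p) if Path(p).is_absolute() else root / p
                if not full.exists():
                    dangling.append(str(p))
        if r.mask_path is None and r.domain == "source" and r.class_label is not None:
            raise ValidationError(
                f"labeled source record {r.image_path} is missing a mask"
            )
    if dangling:
        raise ValidationError("dangling paths in manifest: " + ", ".join(dangling))


def _record_from_row(row: dict) -> ManifestRecord:
    def _none(v):
        if v is None:
            return None
        if isinstance(v, float) and np.isnan(v):
            return None
        if isinstance(v, str) and v.strip() == "":
            return None
        return v

    label = _none(row.get("class_label"))
    return ManifestRecord(
        image_path=str(row["image_path"]),
        domain=str(row["domain"]),
        split=str(row["split"]),
        mask_path=_none(row.get("mask_path")),
        class_label=None if label is None else int(label),
    )


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load and validate a JSON or delimited-text dataset manifest."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such manifest: {path}")
    root = path.parent
    suffix = path.suffix.lower()
    if suffix == ".json":
        text = path.read_text().strip()
        if not text:
            raise ValidationError(f"manifest {path} is empty")
        payload = json.loads(text)
        rows = payload["records"] if isinstance(payload, dict) else payload
    elif suffix in (".csv", ".tsv"):
        if path.stat().st_size == 0:
            raise ValidationError(f"manifest {path} is empty")
        df = pd.read_csv(path, sep="\t" if suffix == ".tsv" else ",")
        missing = {"image_path", "domain", "split"} - set(df.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        rows = df.to_dict("records")
    else:
        raise FormatError(f"unsupported manifest format: {path}")
    records = [_record_from_row(r) for r in rows]
    _validate_records(records, root)
    return DatasetManifest(records=records, root=root)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "records": [
            {
                "image_path": r.image_path,
                "domain": r.domain,
                "split": r.split,
                "mask_path": r.mask_path,
                "class_label": r.class_label,
            }
            for r in manifest.records
        ]
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


# -- anatomical prior tables ---------------------------------------------------

def save_prior_table(pairs, path: str | Path) -> Path:
    """Write (structure_i, structure_j, d_prior) triples as tab-delimited text."""
    df = pd.DataFrame(pairs, columns=["structure_i", "structure_j", "d_prior"])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def load_prior_table(path: str | Path):
    df = pd.read_csv(path, sep="\t")
    missing = {"structure_i", "structure_j", "d_prior"} - set(df.columns)
    if missing:
        raise ValidationError(f"prior table missing columns: {sorted(missing)}")
    return [
        (int(i), int(j), float(d))
        for i, j, d in df[["structure_i", "structure_j", "d_prior"]].itertuples(index=False)
    ]
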