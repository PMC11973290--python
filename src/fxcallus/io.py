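"""Reading and writing micro-CT stacks, masks, calibrations and dataset manifests.

Conventions shared by the whole package:

* volumes are indexed ``(slice, row, col)``, 0-based;
* masks live on exactly the same grid as their paired image;
* voxels are isotropic, sized in millimetres (default 0.01 mm = 10 um);
* image files are multi-page 16-bit unsigned TIFF; a linear calibration
  ``HU = slope * gray + intercept`` connects stored gray levels to
  Hounsfield units (identity by default, i.e. the TIFF already stores HU).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import imageio.v3 as iio

__all__ = [
    "Calibration",
    "HUVolume",
    "ManifestEntry",
    "DatasetManifest",
    "StackShapeError",
    "CalibrationRangeError",
    "ManifestError",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "load_manifest",
    "save_manifest",
    "load_dataset_calibration",
]

VALID_GROUPS = ("F", "F+S")
VALID_SPLITS = ("train", "val", "test")
DEFAULT_VOXEL_SIZE_MM = 0.01

_U16_MAX = 65535


class StackShapeError(ValueError):
    """A multi-page TIFF whose pages do not share one slice shape."""


class CalibrationRangeError(ValueError):
    """HU values that do not fit the 16-bit output range after inverse calibration."""


class ManifestError(ValueError):
    """A dataset manifest that violates its contract."""


@dataclass(frozen=True)
class Calibration:
    """Linear gray-level to Hounsfield-unit map: ``HU = slope * gray + intercept``."""

    slope: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")

    def to_hu(self, gray: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(gray, dtype=np.float64) + self.intercept

    def to_gray(self, hu: np.ndarray) -> np.ndarray:
        return (np.asarray(hu, dtype=np.float64) - self.intercept) / self.slope

    def to_json(self, path: str | Path, voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM) -> None:
        payload = {"slope": self.slope, "intercept": self.intercept, "voxel_size_mm": voxel_size_mm}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> tuple["Calibration", float]:
        payload = json.loads(Path(path).read_text())
        cal = cls(slope=float(payload["slope"]), intercept=float(payload.get("intercept", 0.0)))
        return cal, float(payload.get("voxel_size_mm", DEFAULT_VOXEL_SIZE_MM))


@dataclass
class HUVolume:
    """A calibrated 3-D scalar field in Hounsfield units with isotropic voxel size."""

    data: np.ndarray
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM
    origin_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"HUVolume.data must be 3-D with all dims >= 1, got shape {self.data.shape}")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def _validate_mask(mask: np.ndarray, image_shape: tuple[int, ...] | None = None) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask > 0
    if image_shape is not None and mask.shape != tuple(image_shape):
        raise ValueError(f"mask shape {mask.shape} does not match image shape {tuple(image_shape)}")
    return mask


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    group: str
    day: int
    image_path: str
    roi_path: str
    split: str


@dataclass
class DatasetManifest:
    """Validated list of (subject, day) scan entries with subject-level splits."""

    entries: list[ManifestEntry] = field(default_factory=list)
    root: Path | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def subjects(self, split: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            if split is None or e.split == split:
                seen.setdefault(e.subject_id)
        return list(seen)

    def split_counts(self) -> dict[str, int]:
        """Number of distinct subjects per split."""
        return {s: len(self.subjects(s)) for s in VALID_SPLITS}

    def select(self, split: str | None = None, day: int | None = None) -> list[ManifestEntry]:
        out = []
        for e in self.entries:
            if split is not None and e.split != split:
                continue
            if day is not None and e.day != day:
                continue
            out.append(e)
        return out

    def resolve(self, path: str) -> Path:
        p = Path(path)
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p


def load_dataset_calibration(root: str | Path | None) -> tuple[Calibration, float]:
    """Calibration and voxel size for a dataset directory.

    Reads ``calibration.json`` next to the manifest when present, otherwise
    falls back to the identity calibration and the default voxel size.
    """
    if root is not None:
        cal_path = Path(root) / "calibration.json"
        if cal_path.exists():
            return Calibration.from_json(cal_path)
    return Calibration(), DEFAULT_VOXEL_SIZE_MM


def read_stack(
    path: str | Path,
    cal: Calibration | None = None,
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM,
) -> HUVolume:
    """Read a multi-page TIFF stack and apply the linear HU calibration.

    Raises :class:`StackShapeError` naming the first page whose shape differs
    from page 1 (pages are numbered from 1, as TIFF readers print them).
    """
    cal = cal or Calibration()
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        shapes = [p.shape for p in tf.pages]
        if not shapes:
            raise StackShapeError(f"{path} contains no pages")
        for i, s in enumerate(shapes[1:], start=2):
            if s != shapes[0]:
                raise StackShapeError(
                    f"{path}: page {i} has shape {s}, expected {shapes[0]} (uniform slice shape required)"
                )
        slices = [p.asarray() for p in tf.pages]
    gray = np.stack(slices, axis=0)
    return HUVolume(cal.to_hu(gray), voxel_size_mm=voxel_size_mm, origin_id=str(path))


def write_stack(vol: HUVolume, cal: Calibration | None = None, path: str | Path = "stack.tif") -> None:
    """Write a volume as 16-bit multi-page TIFF through the inverse calibration.

    Gray levels are rounded to the nearest integer, so a read-back differs from
    the original by at most ``0.5 * |slope|`` per voxel.
    """
    cal = cal or Calibration()
    gray = np.rint(cal.to_gray(vol.data))
    if gray.min() < 0 or gray.max() > _U16_MAX:
        raise CalibrationRangeError(
            "volume does not fit the 16-bit output range after inverse calibration: "
            f"gray min={gray.min():.1f}, max={gray.max():.1f} "
            f"(HU min={vol.data.min():.1f}, max={vol.data.max():.1f})"
        )
    tifffile.imwrite(Path(path), gray.astype(np.uint16), photometric="minisblack")


def read_mask(path: str | Path, image_shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Read a binary mask from single-channel TIFF or PNG (any nonzero = foreground)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return _validate_mask(arr, image_shape)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as 0/255 single-channel TIFF or PNG."""
    path = Path(path)
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr, photometric="minisblack")
    else:
        iio.imwrite(path, arr)


def _parse_entry(row: dict, idx: int) -> ManifestEntry:
    try:
        subject_id = str(row["subject_id"]).strip()
        group = str(row["group"]).strip()
        day = int(row["day"])
        image_path = str(row["image_path"]).strip()
        roi_path = str(row["roi_path"]).strip()
        split = str(row["split"]).strip()
    except (KeyError, TypeError, ValueError) as exc:
        raise ManifestError(f"manifest row {idx}: missing or malformed field ({exc})") from exc
    if group not in VALID_GROUPS:
        raise ManifestError(f"manifest row {idx}: unknown group {group!r} (expected one of {VALID_GROUPS})")
    if split not in VALID_SPLITS:
        raise ManifestError(f"manifest row {idx}: unknown split {split!r} (expected one of {VALID_SPLITS})")
    return ManifestEntry(subject_id, group, day, image_path, roi_path, split)


def load_manifest(path: str | Path, check_paths: bool = True) -> DatasetManifest:
    """Load and validate a CSV or JSON dataset manifest.

    Relative image/ROI paths are resolved against the manifest's directory.
    """
    path = Path(path)
    rows: list[dict]
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        rows = payload["entries"] if isinstance(payload, dict) else payload
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    if not rows:
        raise ManifestError(f"{path}: no entries")
    entries = [_parse_entry(row, i) for i, row in enumerate(rows, start=1)]
    seen: set[tuple[str, int]] = set()
    for i, e in enumerate(entries, start=1):
        key = (e.subject_id, e.day)
        if key in seen:
            raise ManifestError(f"manifest row {i}: duplicate (subject_id, day) = {key}")
        seen.add(key)
    manifest = DatasetManifest(entries=entries, root=path.parent)
    if check_paths:
        for i, e in enumerate(entries, start=1):
            for p in (e.image_path, e.roi_path):
                if not manifest.resolve(p).exists():
                    raise ManifestError(f"manifest row {i}: path not resolvable: {p}")
    return manifest


def save_manifest(manifest: DatasetManifest | Sequence[ManifestEntry], path: str | Path) -> None:
    entries = manifest.entries if isinstance(manifest, DatasetManifest) else list(manifest)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "day", "image_path", "roi_path", "split"])
        for e in entries:
            writer.writerow([e.subject_id, e.group, e.day, e.image_path, e.roi_path, e.split])
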