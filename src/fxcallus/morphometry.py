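"""HU-window tissue classification and bone morphometric indices.

Inside an annotated lesion ROI, voxels are classified into four callus
compartments by their Hounsfield value: inflammatory hematoma (0-224 HU),
cartilage (225-330 HU), mineralized cartilage (331-700 HU) and osteogenic
tissue (701-1000 HU). Values below 0 or above 1000 HU inside the ROI
(soft-tissue background, intact cortical bone) stay unclassified.

From the class map we derive, per tissue:

* avg CT    -- mean HU over the tissue's voxels;
* BV, TV    -- tissue volume and total classified volume (mm^3);
* BS, TS    -- mean per-slice tissue area and total classified area (mm^2),
               averaged over slices that contain any classified voxel;
* BS/TS (%) -- area fraction; BV/TV (%) -- volume fraction;
* BS/TV (1/mm) -- area-to-volume ratio.

With these conventions BS/TS and BV/TV each sum to 100% across the four
tissues whenever TV > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import Calibration, DatasetManifest, HUVolume, read_mask, read_stack

__all__ = [
    "TISSUE_LABELS",
    "TISSUE_NAMES",
    "HU_WINDOWS",
    "TissueClassMap",
    "MorphometricRecord",
    "classify_tissues",
    "average_ct",
    "area_volume_indices",
    "batch_morphometry",
]

# label 0 is reserved for background / unclassified
TISSUE_LABELS: dict[str, int] = {
    "hematoma": 1,
    "cartilage": 2,
    "mineralized_cartilage": 3,
    "osteogenic": 4,
}
TISSUE_NAMES: dict[int, str] = {v: k for k, v in TISSUE_LABELS.items()}

# Half-open real-valued partition of the classified HU range; the last window
# is closed at 1000 so the full classified range is [0, 1000].
HU_WINDOWS: dict[int, tuple[float, float]] = {
    1: (0.0, 225.0),
    2: (225.0, 331.0),
    3: (331.0, 701.0),
    4: (701.0, 1000.0),
}


@dataclass
class TissueClassMap:
    """Per-voxel tissue label map restricted to an ROI."""

    labels: np.ndarray
    voxel_size_mm: float
    windows: Mapping[int, tuple[float, float]] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.windows is None:
            self.windows = dict(HU_WINDOWS)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


@dataclass
class MorphometricRecord:
    """One (subject, day, tissue) row of the morphometry table."""

    subject_id: str
    group: str
    day: int
    tissue: str
    avg_ct_hu: float  # NaN flags an undefined (zero-voxel) mean
    bs_mm2: float
    ts_mm2: float
    bv_mm3: float
    tv_mm3: float
    bs_ts_pct: float
    bv_tv_pct: float
    bs_tv_per_mm: float
    mask_source: str = "annotation"


def classify_tissues(vol: HUVolume, roi: np.ndarray) -> TissueClassMap:
    """Assign each in-ROI voxel to a tissue by its HU window."""
    roi = np.asarray(roi).astype(bool)
    if roi.shape != vol.data.shape:
        raise ValueError(f"ROI shape {roi.shape} does not match volume shape {vol.data.shape}")
    hu = vol.data
    labels = np.zeros(hu.shape, dtype=np.uint8)
    for label, (lo, hi) in HU_WINDOWS.items():
        if label == max(HU_WINDOWS):
            inside = (hu >= lo) & (hu <= hi)
        else:
            inside = (hu >= lo) & (hu < hi)
        labels[inside & roi] = label
    return TissueClassMap(labels=labels, voxel_size_mm=vol.voxel_size_mm)


def average_ct(vol: HUVolume, cmap: TissueClassMap, tissue: str | int) -> float:
    """Mean HU over one tissue's voxels; NaN when the tissue has no voxels."""
    label = TISSUE_LABELS[tissue] if isinstance(tissue, str) else int(tissue)
    sel = cmap.labels == label
    if not sel.any():
        return float("nan")
    return float(vol.data[sel].mean())


def area_volume_indices(cmap: TissueClassMap, voxel_size_mm: float | None = None) -> list[dict]:
    """Per-tissue BS, TS, BV, TV and the three ratios.

    BS is the mean per-slice tissue area over slices containing any classified
    voxel; BV is the total tissue voxel volume. Ratios are NaN when TV = 0.
    """
    vs = cmap.voxel_size_mm if voxel_size_mm is None else voxel_size_mm
    labels = cmap.labels
    if labels.ndim == 2:
        labels = labels[None]
    active = np.array([np.any(labels[s] > 0) for s in range(labels.shape[0])])
    records = []
    counts = {lab: int(np.sum(labels == lab)) for lab in TISSUE_NAMES}
    tv = sum(counts.values()) * vs**3
    if active.any():
        slice_counts = {
            lab: np.array([np.sum(labels[s] == lab) for s in np.flatnonzero(active)])
            for lab in TISSUE_NAMES
        }
        bs = {lab: float(slice_counts[lab].mean()) * vs**2 for lab in TISSUE_NAMES}
    else:
        bs = {lab: 0.0 for lab in TISSUE_NAMES}
    ts = sum(bs.values())
    for lab, name in TISSUE_NAMES.items():
        bv = counts[lab] * vs**3
        records.append(
            {
                "tissue": name,
                "bs_mm2": bs[lab],
                "ts_mm2": ts,
                "bv_mm3": bv,
                "tv_mm3": tv,
                "bs_ts_pct": 100.0 * bs[lab] / ts if ts > 0 else float("nan"),
                "bv_tv_pct": 100.0 * bv / tv if tv > 0 else float("nan"),
                "bs_tv_per_mm": bs[lab] / tv if tv > 0 else float("nan"),
            }
        )
    return records


def records_to_frame(records: list[MorphometricRecord]) -> pd.DataFrame:
    cols = [
        "subject_id", "group", "day", "tissue", "avg_ct_hu", "bs_mm2", "ts_mm2",
        "bv_mm3", "tv_mm3", "bs_ts_pct", "bv_tv_pct", "bs_tv_per_mm", "mask_source",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def morphometry_for_volume(
    vol: HUVolume,
    roi: np.ndarray,
    subject_id: str = "",
    group: str = "F",
    day: int = 0,
    mask_source: str = "annotation",
) -> list[MorphometricRecord]:
    """Classify one volume and emit its four tissue records."""
    cmap = classify_tissues(vol, roi)
    fragments = area_volume_indices(cmap)
    out = []
    for frag in fragments:
        out.append(
            MorphometricRecord(
                subject_id=subject_id,
                group=group,
                day=day,
                avg_ct_hu=average_ct(vol, cmap, frag["tissue"]),
                mask_source=mask_source,
                **frag,
            )
        )
    return out


def batch_morphometry(
    manifest: DatasetManifest,
    masks_source: str | Mapping[tuple[str, int], np.ndarray] = "annotation",
    cal: Calibration | None = None,
    voxel_size_mm: float | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Morphometry table over a whole dataset: one row per (subject, day, tissue).

    ``masks_source`` is either ``"annotation"`` (use each entry's ROI file) or a
    mapping ``(subject_id, day) -> mask array`` holding predicted masks; the
    provenance lands in the ``mask_source`` column. Entries whose mask is
    missing are skipped with a warning.
    """
    records: list[MorphometricRecord] = []
    source_name = masks_source if isinstance(masks_source, str) else "predicted"
    from .io import load_dataset_calibration

    auto_cal, auto_vox = load_dataset_calibration(manifest.root)
    for entry in manifest.entries:
        vol = read_stack(
            manifest.resolve(entry.image_path),
            cal=cal if cal is not None else auto_cal,
            voxel_size_mm=voxel_size_mm if voxel_size_mm is not None else auto_vox,
        )
        if isinstance(masks_source, str):
            if masks_source != "annotation":
                raise ValueError("masks_source must be 'annotation' or a mapping of predicted masks")
            roi = read_mask(manifest.resolve(entry.roi_path), image_shape=vol.shape)
        else:
            key = (entry.subject_id, entry.day)
            if key not in masks_source:
                warnings.warn(f"no predicted mask for {key}; entry skipped")
                continue
            roi = np.asarray(masks_source[key]).astype(bool)
        records.extend(
            morphometry_for_volume(
                vol, roi,
                subject_id=entry.subject_id, group=entry.group, day=entry.day,
                mask_source=source_name,
            )
        )
    frame = records_to_frame(records)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return frame
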