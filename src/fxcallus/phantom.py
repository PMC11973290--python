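"""Synthetic fracture micro-CT phantoms.

The generator emulates the rat medial-malleolus fracture model: a tubular
bone cross-section (cortical shell > 1000 HU around a trabecular interior)
cut by a ~1 mm-wide notch lesion, imaged on soft-tissue background (< 0 HU).
Inside the lesion ROI, voxels are painted with the four callus compartments
(hematoma, cartilage, mineralized cartilage, osteogenic tissue), each drawn
strictly inside its HU classification window, layered from the intact bone
inward: osteogenic closest to bone, hematoma and an unclassified soft-tissue
gap at the core. Healing is encoded in the per-(group, day) composition
table: the fracture-only (F) group's gap shrinks over the six imaging days
(day 35 ~ bridged), while the artery-transected (F+S) group keeps a
persistent gap and a larger soft-tissue share — the non-union contrast.

Default composition fractions and tissue HU statistics follow the measured
group/day morphometry of the rat study the phantom emulates; sampled feature
tables reproduce those per-index means and spreads directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

from .io import (
    Calibration,
    DatasetManifest,
    HUVolume,
    ManifestEntry,
    save_manifest,
    write_mask,
    write_stack,
)
from .morphometry import HU_WINDOWS, TISSUE_LABELS, TissueClassMap

__all__ = [
    "DAYS",
    "TISSUES",
    "FEATURE_NAMES",
    "FEATURE_STATS",
    "CompositionEntry",
    "DEFAULT_COMPOSITION",
    "PhantomConfig",
    "TrainingSample",
    "make_phantom",
    "derive_aux_masks",
    "phantom_training_samples",
    "sample_feature_table",
    "make_dataset",
    "feature_stats_frame",
]

DAYS = (1, 7, 14, 21, 28, 35)
TISSUES = ("hematoma", "cartilage", "mineralized_cartilage", "osteogenic")

# ----------------------------------------------------------------- statistics
# Reference per-(group, day) statistics of the rat fracture model, as
# (mean, sd) over days (1, 7, 14, 21, 28, 35). Units: HU for avg CT,
# % for BS/TS and BV/TV, 1/mm for BS/TV.
_AVG_CT = {
    "hematoma": {
        "F": [(88.5, 30.2), (79.0, 12.9), (103.0, 29.7), (85.9, 32.1), (105.0, 24.7), (92.8, 38.4)],
        "F+S": [(76.0, 38.0), (59.2, 35.4), (54.0, 21.6), (64.8, 38.4), (71.3, 18.6), (82.5, 33.6)],
    },
    "cartilage": {
        "F": [(211.0, 50.0), (174.0, 88.9), (203.0, 73.8), (204.0, 89.7), (196.0, 30.3), (203.0, 70.3)],
        "F+S": [(155.0, 47.5), (149.0, 109.0), (144.0, 129.0), (145.0, 126.0), (156.0, 87.6), (198.0, 85.0)],
    },
    "mineralized_cartilage": {
        "F": [(482.0, 61.7), (465.0, 80.2), (491.0, 88.0), (513.0, 78.9), (457.0, 48.7), (495.0, 50.0)],
        "F+S": [(383.0, 72.5), (448.0, 123.0), (482.0, 126.0), (500.0, 88.9), (435.0, 94.9), (534.0, 45.7)],
    },
    "osteogenic": {
        "F": [(672.0, 88.9), (672.0, 84.6), (698.0, 83.7), (720.0, 58.2), (633.0, 64.3), (685.0, 75.1)],
        "F+S": [(564.0, 90.6), (642.0, 129.0), (681.0, 120.0), (685.0, 89.7), (620.0, 103.0), (737.0, 55.2)],
    },
}

_BS_TS = {
    "hematoma": {
        "F": [(4.83, 5.58), (5.54, 4.56), (3.97, 5.00), (2.31, 2.55), (6.89, 4.80), (3.66, 2.91)],
        "F+S": [(13.0, 8.07), (8.35, 9.4), (5.29, 5.40), (4.13, 3.36), (10.5, 7.35), (1.47, 1.55)],
    },
    "cartilage": {
        "F": [(5.27, 3.71), (5.26, 3.11), (4.16, 3.23), (3.14, 2.11), (6.25, 2.38), (4.33, 2.30)],
        "F+S": [(8.94, 3.59), (6.11, 4.34), (5.74, 4.72), (5.00, 3.35), (7.46, 3.79), (2.64, 2.07)],
    },
    "mineralized_cartilage": {
        "F": [(35.0, 7.81), (32.4, 8.45), (32.1, 6.76), (30.4, 7.81), (37.2, 4.29), (33.2, 7.78)],
        "F+S": [(36.2, 5.73), (32.9, 10.1), (32.9, 13.5), (35.4, 11.2), (33.9, 7.37), (30.8, 8.01)],
    },
    "osteogenic": {
        "F": [(54.9, 15.1), (56.8, 14.2), (59.8, 12.7), (64.2, 11.0), (49.6, 9.19), (58.8, 11.9)],
        "F+S": [(41.8, 11.1), (52.6, 18.8), (56.1, 21.7), (55.5, 16.7), (48.1, 15.5), (65.1, 10.8)],
    },
}

_BS_TV = {
    "mineralized_cartilage": {
        "F": [(0.300, 0.325), (0.313, 0.257), (0.381, 0.292), (0.344, 0.335), (0.346, 0.187), (0.346, 0.274)],
        "F+S": [(0.570, 0.336), (0.328, 0.321), (0.355, 0.270), (0.266, 0.192), (0.290, 0.260), (0.224, 0.242)],
    },
    "osteogenic": {
        "F": [(0.336, 0.237), (0.490, 0.400), (0.598, 0.367), (0.674, 0.574), (0.439, 0.232), (0.519, 0.333)],
        "F+S": [(0.648, 0.367), (0.400, 0.262), (0.410, 0.240), (0.311, 0.203), (0.310, 0.195), (0.370, 0.243)],
    },
}

_BV_TV = {
    "hematoma": {
        "F": [(8.66, 4.23), (6.05, 2.14), (5.85, 3.73), (3.04, 1.14), (7.55, 1.95), (4.79, 2.40)],
        "F+S": [(11.8, 3.32), (8.80, 4.00), (7.27, 3.71), (5.25, 3.50), (12.8, 4.03), (2.30, 4.96)],
    },
    "cartilage": {
        "F": [(8.01, 2.24), (5.83, 1.55), (5.50, 1.60), (3.77, 0.843), (6.50, 0.755), (5.30, 1.30)],
        "F+S": [(9.00, 2.53), (7.14, 1.14), (7.88, 1.93), (6.41, 1.27), (9.15, 2.32), (3.82, 1.45)],
    },
    "mineralized_cartilage": {
        "F": [(39.3, 5.90), (34.3, 5.51), (34.5, 0.41), (31.5, 3.35), (37.9, 0.83), (36.0, 4.52)],
        "F+S": [(37.0, 3.87), (37.9, 5.63), (39.4, 1.01), (40.7, 1.37), (37.7, 2.41), (35.4, 5.38)],
    },
    "osteogenic": {
        "F": [(44.0, 8.36), (53.8, 9.19), (54.2, 4.92), (61.7, 3.83), (48.1, 1.88), (54.0, 8.22)],
        "F+S": [(42.1, 9.72), (46.2, 3.70), (45.5, 3.64), (47.6, 3.28), (40.3, 5.12), (58.5, 5.00)],
    },
}

# The ten indices used by the early-diagnosis model: avg CT of hematoma and
# cartilage, BS/TS of all four tissues, BS/TV of mineralized cartilage and
# osteogenic tissue, BV/TV of osteogenic tissue, plus BV/TV of mineralized
# cartilage as the tenth (configurable) index.
FEATURE_NAMES = (
    "avg_ct_hematoma",
    "avg_ct_cartilage",
    "bs_ts_hematoma",
    "bs_ts_cartilage",
    "bs_ts_mineralized",
    "bs_ts_osteogenic",
    "bs_tv_mineralized",
    "bs_tv_osteogenic",
    "bv_tv_osteogenic",
    "bv_tv_mineralized",
)


def _build_feature_stats() -> dict[tuple[str, int], dict[str, tuple[float, float]]]:
    src = {
        "avg_ct_hematoma": _AVG_CT["hematoma"],
        "avg_ct_cartilage": _AVG_CT["cartilage"],
        "bs_ts_hematoma": _BS_TS["hematoma"],
        "bs_ts_cartilage": _BS_TS["cartilage"],
        "bs_ts_mineralized": _BS_TS["mineralized_cartilage"],
        "bs_ts_osteogenic": _BS_TS["osteogenic"],
        "bs_tv_mineralized": _BS_TV["mineralized_cartilage"],
        "bs_tv_osteogenic": _BS_TV["osteogenic"],
        "bv_tv_osteogenic": _BV_TV["osteogenic"],
        "bv_tv_mineralized": _BV_TV["mineralized_cartilage"],
    }
    stats: dict[tuple[str, int], dict[str, tuple[float, float]]] = {}
    for group in ("F", "F+S"):
        for d_idx, day in enumerate(DAYS):
            stats[(group, day)] = {name: src[name][group][d_idx] for name in FEATURE_NAMES}
    return stats


FEATURE_STATS = _build_feature_stats()

# feature value bounds for truncated sampling: avg CT to the physical
# classified range, percentages to [0, 100], surface-to-volume ratios to [0, inf)
_FEATURE_BOUNDS = {
    "avg_ct": (0.0, 1000.0),
    "bs_ts": (0.0, 100.0),
    "bv_tv": (0.0, 100.0),
    "bs_tv": (0.0, np.inf),
}


def _feature_bounds(name: str) -> tuple[float, float]:
    return _FEATURE_BOUNDS["_".join(name.split("_")[:2])]


# ---------------------------------------------------------------- composition
@dataclass(frozen=True)
class CompositionEntry:
    """Target lesion composition for one (group, day).

    ``fractions`` are the four classified-tissue shares (sum to 1);
    ``gap_fraction`` is the unclassified soft-tissue share of the ROI — the
    unbridged part of the lesion; ``hu_mean``/``hu_sd`` parameterize the
    per-tissue HU draws (truncated inside each tissue's window).
    """

    fractions: dict[str, float]
    gap_fraction: float
    hu_mean: dict[str, float]
    hu_sd: dict[str, float]

    def validate(self) -> None:
        total = sum(self.fractions[t] for t in TISSUES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tissue fractions sum to {total!r}, expected 1")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must lie in [0, 1)")


_GAP_FRACTIONS = {
    # F bridges by day 35; F+S keeps a persistent unclassified gap (non-union)
    "F": dict(zip(DAYS, (0.60, 0.45, 0.30, 0.18, 0.10, 0.05))),
    "F+S": dict(zip(DAYS, (0.60, 0.55, 0.52, 0.50, 0.48, 0.45))),
}


def _build_default_composition() -> dict[tuple[str, int], CompositionEntry]:
    table: dict[tuple[str, int], CompositionEntry] = {}
    for group in ("F", "F+S"):
        for d_idx, day in enumerate(DAYS):
            raw = {t: _BV_TV[t][group][d_idx][0] for t in TISSUES}
            total = sum(raw.values())
            table[(group, day)] = CompositionEntry(
                fractions={t: raw[t] / total for t in TISSUES},
                gap_fraction=_GAP_FRACTIONS[group][day],
                hu_mean={t: _AVG_CT[t][group][d_idx][0] for t in TISSUES},
                hu_sd={t: _AVG_CT[t][group][d_idx][1] for t in TISSUES},
            )
    return table


DEFAULT_COMPOSITION = _build_default_composition()

_BACKGROUND_HU = -100.0
_TRABECULAR_HU = 1100.0
_CORTICAL_HU = 1500.0
_GAP_HU_RANGE = (-150.0, -50.0)
_WINDOW_MARGIN = 1.0  # HU margin keeping draws strictly inside a window


# -------------------------------------------------------------------- configs
@dataclass(frozen=True)
class PhantomConfig:
    """Conditions for one synthetic scan.

    The default voxel size (0.04 mm) renders the 10 um acquisition at 4x
    coarser sampling so a 64 x 64 slice spans 2.56 mm — enough to host a
    ~2 mm bone cross-section with a 1 mm notch at desk scale.
    """

    group: str = "F"
    day: int = 14
    shape: tuple[int, int, int] = (8, 64, 64)
    voxel_size_mm: float = 0.04
    notch_width_mm: float = 1.0
    noise_sd_hu: float = 0.0
    seed: int = 0
    outer_radius_frac: float = 0.42  # of min(rows, cols)
    inner_radius_frac: float = 0.55  # of the outer radius
    composition_table: dict[tuple[str, int], CompositionEntry] = field(
        default_factory=lambda: DEFAULT_COMPOSITION
    )

    def __post_init__(self) -> None:
        if self.group not in ("F", "F+S"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.day not in DAYS:
            raise ValueError(f"day must be one of {DAYS}")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        if not self.notch_width_mm < self.shape[2] * self.voxel_size_mm:
            raise ValueError("notch_width_mm must be smaller than the in-plane field of view")


@dataclass
class TrainingSample:
    """One 2-D training example: image slice, ROI, and auxiliary supervision maps."""

    image: np.ndarray
    roi: np.ndarray
    edge_gt: np.ndarray
    noise_gt: np.ndarray  # M_n
    texture_gt: np.ndarray  # M_t
    subject_id: str = ""
    day: int = 0
    group: str = "F"

    def __post_init__(self) -> None:
        shape = np.asarray(self.image).shape
        for name in ("roi", "edge_gt", "noise_gt", "texture_gt"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} does not match image shape {shape}")


def _allocate_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n voxels to the tissue fractions."""
    raw = {t: n * fractions[t] for t in TISSUES}
    counts = {t: int(np.floor(raw[t])) for t in TISSUES}
    remainder = n - sum(counts.values())
    order = sorted(TISSUES, key=lambda t: raw[t] - counts[t], reverse=True)
    for t in order[:remainder]:
        counts[t] += 1
    return counts


def _draw_window_hu(
    rng: np.random.Generator, tissue: str, mean: float, sd: float, size: int
) -> np.ndarray:
    lo, hi = HU_WINDOWS[TISSUE_LABELS[tissue]]
    lo, hi = lo + _WINDOW_MARGIN, hi - _WINDOW_MARGIN
    sd = max(sd, 1e-6)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def make_phantom(cfg: PhantomConfig) -> tuple[HUVolume, np.ndarray, TissueClassMap]:
    """Generate one synthetic scan: HU volume, lesion ROI mask, and the true tissue map.

    Deterministic given ``cfg.seed``. At ``noise_sd_hu = 0`` every in-ROI voxel
    lies strictly inside its tissue's HU window, so HU-window classification
    reproduces the returned truth map exactly.
    """
    key = (cfg.group, cfg.day)
    if key not in cfg.composition_table:
        raise ValueError(f"composition table has no entry for {key}")
    comp = cfg.composition_table[key]
    comp.validate()

    S, R, C = cfg.shape
    wpx = max(2, int(round(cfg.notch_width_mm / cfg.voxel_size_mm)))
    r_out = cfg.outer_radius_frac * min(R, C)
    r_in = cfg.inner_radius_frac * r_out
    if wpx >= C or r_out < 3:
        raise ValueError(f"shape {cfg.shape} too small to host a {cfg.notch_width_mm} mm notch")

    cy, cx = (R - 1) / 2.0, (C - 1) / 2.0
    rows, cols = np.mgrid[0:R, 0:C]
    radius = np.hypot(rows - cy, cols - cx)
    bone2d = radius <= r_out
    shell2d = bone2d & (radius > r_in)
    slot2d = (np.abs(cols - cx) < wpx / 2.0) & (rows <= cy)
    roi2d = slot2d & bone2d
    if not roi2d.any():
        raise ValueError(f"shape {cfg.shape} too small to host the notch lesion")

    slice2d = np.full((R, C), _BACKGROUND_HU)
    slice2d[bone2d] = _TRABECULAR_HU
    slice2d[shell2d] = _CORTICAL_HU
    vol = np.tile(slice2d, (S, 1, 1))
    roi = np.tile(roi2d, (S, 1, 1))

    # healing layers: distance from each ROI voxel to the nearest intact bone voxel
    intact_bone = np.tile(bone2d & ~roi2d, (S, 1, 1))
    dist = ndimage.distance_transform_edt(~intact_bone)
    flat_roi = np.flatnonzero(roi)
    order = flat_roi[np.lexsort((flat_roi, dist.ravel()[flat_roi]))]

    n = order.size
    n_gap = int(round(comp.gap_fraction * n))
    counts = _allocate_counts(n - n_gap, comp.fractions)

    rng = np.random.default_rng(cfg.seed)
    labels = np.zeros(vol.shape, dtype=np.uint8)
    flat_vol = vol.ravel()
    flat_lab = labels.ravel()
    pos = 0
    for tissue in ("osteogenic", "mineralized_cartilage", "cartilage", "hematoma"):
        k = counts[tissue]
        idx = order[pos:pos + k]
        flat_vol[idx] = _draw_window_hu(rng, tissue, comp.hu_mean[tissue], comp.hu_sd[tissue], k)
        flat_lab[idx] = TISSUE_LABELS[tissue]
        pos += k
    gap_idx = order[pos:]
    flat_vol[gap_idx] = rng.uniform(*_GAP_HU_RANGE, size=gap_idx.size)

    if cfg.noise_sd_hu > 0:
        vol = vol + rng.normal(0.0, cfg.noise_sd_hu, size=vol.shape)

    hu = HUVolume(vol, voxel_size_mm=cfg.voxel_size_mm,
                  origin_id=f"phantom:{cfg.group}:day{cfg.day}:seed{cfg.seed}")
    return hu, roi, TissueClassMap(labels=labels, voxel_size_mm=cfg.voxel_size_mm)


# ------------------------------------------------------------ auxiliary masks
def derive_aux_masks(
    image: np.ndarray,
    roi: np.ndarray,
    median_size: int = 3,
    texture_window: int = 5,
    band_px: int = 5,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ground-truth supervision maps for the EFDM branches of one slice.

    * edge: the ROI's 1-pixel inner boundary (mask minus its erosion);
    * noise M_n: magnitude of the residual against a median-filtered copy,
      restricted to a dilated band around the ROI;
    * texture M_t: local standard deviation of the median-filtered image in a
      ``texture_window`` window, restricted to the ROI.

    With ``normalize`` the scalar maps are max-rescaled to [0, 1] (all-zero maps
    stay zero). An empty ROI yields all-zero maps and a warning.
    """
    image = np.asarray(image, dtype=np.float64)
    roi = np.asarray(roi).astype(bool)
    if roi.shape != image.shape:
        raise ValueError("ROI shape must match image shape")
    if not roi.any():
        warnings.warn("empty ROI: auxiliary masks are all zero")
        z = np.zeros_like(image)
        return z.astype(bool), z.copy(), z.copy()

    edge = roi & ~ndimage.binary_erosion(roi, border_value=0)

    denoised = ndimage.median_filter(image, size=median_size)
    band = ndimage.binary_dilation(roi, iterations=band_px)
    m_n = np.abs(image - denoised)
    m_n[~band] = 0.0

    local_mean = ndimage.uniform_filter(denoised, size=texture_window)
    local_sq = ndimage.uniform_filter(denoised**2, size=texture_window)
    m_t = np.sqrt(np.maximum(local_sq - local_mean**2, 0.0))
    m_t[~roi] = 0.0

    if normalize:
        for m in (m_n, m_t):
            peak = m.max()
            if peak > 0:
                m /= peak
    return edge, m_n, m_t


def phantom_training_samples(cfg: PhantomConfig, aux_params: dict | None = None) -> list[TrainingSample]:
    """Per-slice training samples (with derived auxiliary maps) from one phantom."""
    vol, roi, _ = make_phantom(cfg)
    samples = []
    for s in range(vol.shape[0]):
        if not roi[s].any():
            continue
        edge, m_n, m_t = derive_aux_masks(vol.data[s], roi[s], **(aux_params or {}))
        samples.append(
            TrainingSample(
                image=vol.data[s], roi=roi[s], edge_gt=edge, noise_gt=m_n, texture_gt=m_t,
                subject_id=f"phantom_{cfg.group}_{cfg.seed}", day=cfg.day, group=cfg.group,
            )
        )
    return samples


# --------------------------------------------------------------- feature sets
def sample_feature_table(
    group: str,
    day: int,
    n: int,
    seed: int = 0,
    table: dict[tuple[str, int], dict[str, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Draw n feature vectors for one (group, day) from the reference statistics.

    Each of the ten indices is sampled from a Gaussian with the table's
    mean/sd, truncated at physical bounds (HU in [0, 1000], percentages in
    [0, 100], ratios >= 0). Deterministic given ``seed``.
    """
    table = table if table is not None else FEATURE_STATS
    key = (group, day)
    if key not in table:
        raise ValueError(f"no feature statistics for group={group!r}, day={day}")
    stats = table[key]
    missing = [f for f in FEATURE_NAMES if f not in stats]
    if missing:
        raise ValueError(f"feature statistics for {key} missing indices: {missing}")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for name in FEATURE_NAMES:
        mean, sd = stats[name]
        lo, hi = _feature_bounds(name)
        if sd <= 0:
            data[name] = np.full(n, float(mean))
        else:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            data[name] = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    frame = pd.DataFrame(data)
    frame.insert(0, "subject_id", [f"{group}-d{day}-{i:04d}" for i in range(n)])
    frame.insert(1, "group", group)
    frame.insert(2, "day", day)
    frame["label"] = 0 if group == "F" else 1
    return frame


def feature_stats_frame(table=None) -> pd.DataFrame:
    """The reference statistics in long form: group, day, index, mean, sd."""
    table = table if table is not None else FEATURE_STATS
    rows = []
    for (group, day), stats in table.items():
        for name, (mean, sd) in stats.items():
            rows.append({"group": group, "day": day, "index": name, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- dataset
def _split_counts(n: int, ratio: tuple[int, int, int]) -> tuple[int, int, int]:
    total = sum(ratio)
    raw = [n * r / total for r in ratio]
    counts = [int(np.floor(x)) for x in raw]
    order = np.argsort([c - x for c, x in zip(counts, raw)])  # most-underallocated first
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return tuple(counts)  # type: ignore[return-value]


def _jitter_composition(entry: CompositionEntry, rng: np.random.Generator) -> CompositionEntry:
    """Mild per-subject variability around the group/day composition."""
    fr = {t: max(entry.fractions[t] * rng.normal(1.0, 0.05), 1e-4) for t in TISSUES}
    total = sum(fr.values())
    fr = {t: v / total for t, v in fr.items()}
    gap = float(np.clip(entry.gap_fraction + rng.uniform(-0.03, 0.03), 0.01, 0.9))
    return CompositionEntry(fractions=fr, gap_fraction=gap, hu_mean=dict(entry.hu_mean), hu_sd=dict(entry.hu_sd))


def make_dataset(
    n_subjects_per_group: int,
    days: tuple[int, ...] = DAYS,
    out_dir: str | Path = "phantom_dataset",
    seed: int = 0,
    cfg: PhantomConfig | None = None,
    split_ratio: tuple[int, int, int] = (9, 1, 2),
    overwrite: bool = False,
) -> DatasetManifest:
    """Write a phantom dataset to disk: per-(subject, day) stacks, ROI masks,
    a calibration JSON (intercept -1000 so negative HU fit the 16-bit range),
    and a CSV manifest with subject-disjoint train/val/test splits."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace it")
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    base = cfg or PhantomConfig()
    cal = Calibration(slope=1.0, intercept=-1000.0)
    cal.to_json(out_dir / "calibration.json", voxel_size_mm=base.voxel_size_mm)

    rng = np.random.default_rng(seed)
    subjects = [(f"F{i + 1:02d}", "F") for i in range(n_subjects_per_group)]
    subjects += [(f"FS{i + 1:02d}", "F+S") for i in range(n_subjects_per_group)]
    order = rng.permutation(len(subjects))
    n_train, n_val, n_test = _split_counts(len(subjects), split_ratio)
    split_of = {}
    for rank, idx in enumerate(order):
        split_of[subjects[idx][0]] = (
            "train" if rank < n_train else "val" if rank < n_train + n_val else "test"
        )

    entries = []
    for subject_id, group in subjects:
        subject_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        for day in days:
            entry_cfg = replace(base, group=group, day=day, seed=int(subject_rng.integers(0, 2**31 - 1)))
            comp = _jitter_composition(entry_cfg.composition_table[(group, day)], subject_rng)
            table = dict(entry_cfg.composition_table)
            table[(group, day)] = comp
            entry_cfg = replace(entry_cfg, composition_table=table)
            vol, roi, _ = make_phantom(entry_cfg)
            img_rel = f"images/{subject_id}_d{day:02d}.tif"
            roi_rel = f"masks/{subject_id}_d{day:02d}.tif"
            for rel in (img_rel, roi_rel):
                if (out_dir / rel).exists() and not overwrite:
                    raise FileExistsError(f"{out_dir / rel} exists; pass overwrite=True")
            write_stack(vol, cal, out_dir / img_rel)
            write_mask(roi, out_dir / roi_rel)
            entries.append(
                ManifestEntry(subject_id, group, day, img_rel, roi_rel, split_of[subject_id])
            )
    save_manifest(entries, manifest_path)
    return DatasetManifest(entries=entries, root=out_dir)
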