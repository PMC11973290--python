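"""HU-window classification and morphometric indices vs a naive oracle."""

import numpy as np
import pandas as pd
import pytest

from fxcallus.io import HUVolume
from fxcallus.morphometry import (
    HU_WINDOWS,
    TISSUE_LABELS,
    TISSUE_NAMES,
    area_volume_indices,
    average_ct,
    batch_morphometry,
    classify_tissues,
    morphometry_for_volume,
)


# --------------------------------------------------------------------- oracle
def oracle_indices(labels: np.ndarray, vs: float) -> dict[str, dict[str, float]]:
    """Naive triple-loop reimplementation of every index."""
    S, R, C = labels.shape
    counts = {lab: 0 for lab in TISSUE_NAMES}
    slice_counts = {lab: [] for lab in TISSUE_NAMES}
    for s in range(S):
        per_slice = {lab: 0 for lab in TISSUE_NAMES}
        any_classified = False
        for r in range(R):
            for c in range(C):
                lab = int(labels[s, r, c])
                if lab:
                    per_slice[lab] += 1
                    counts[lab] += 1
                    any_classified = True
        if any_classified:
            for lab in TISSUE_NAMES:
                slice_counts[lab].append(per_slice[lab])
    out = {}
    tv = sum(counts.values()) * vs**3
    bs = {
        lab: (float(np.mean(np.asarray(slice_counts[lab]))) * vs**2 if slice_counts[lab] else 0.0)
        for lab in TISSUE_NAMES
    }
    ts = sum(bs.values())
    for lab, name in TISSUE_NAMES.items():
        bv = counts[lab] * vs**3
        out[name] = {
            "bs_mm2": bs[lab],
            "ts_mm2": ts,
            "bv_mm3": bv,
            "tv_mm3": tv,
            "bs_ts_pct": 100.0 * bs[lab] / ts if ts > 0 else np.nan,
            "bv_tv_pct": 100.0 * bv / tv if tv > 0 else np.nan,
            "bs_tv_per_mm": bs[lab] / tv if tv > 0 else np.nan,
        }
    return out


def oracle_avg_ct(hu: np.ndarray, labels: np.ndarray, lab: int) -> float:
    vals = []
    S, R, C = labels.shape
    for s in range(S):
        for r in range(R):
            for c in range(C):
                if labels[s, r, c] == lab:
                    vals.append(hu[s, r, c])
    return float(np.mean(np.asarray(vals))) if vals else float("nan")


def random_case(rng):
    hu = rng.uniform(-200, 1500, size=(16, 16, 16))
    roi = rng.random((16, 16, 16)) > 0.5
    vol = HUVolume(hu, voxel_size_mm=0.01)
    return vol, roi


class TestClassification:
    def test_window_membership(self):
        """Representative HU values land in their tissue windows."""
        hu = np.array([[[100.0, 250.0, 400.0, 800.0]]])
        vol = HUVolume(hu)
        cmap = classify_tissues(vol, np.ones_like(hu, bool))
        assert list(cmap.labels[0, 0]) == [1, 2, 3, 4]

    def test_out_of_range_is_background(self):
        hu = np.array([[[-50.0, 1500.0, 1000.0, 1000.5]]])
        vol = HUVolume(hu)
        cmap = classify_tissues(vol, np.ones_like(hu, bool))
        assert list(cmap.labels[0, 0]) == [0, 0, 4, 0]

    def test_window_boundaries_partition(self):
        """Every HU in [0, 1000] maps to exactly one tissue (half-open windows)."""
        edges = np.array([[[0.0, 224.9, 225.0, 330.9, 331.0, 700.9, 701.0, 1000.0]]])
        vol = HUVolume(edges)
        cmap = classify_tissues(vol, np.ones_like(edges, bool))
        assert list(cmap.labels[0, 0]) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_empty_roi_all_background(self, rng):
        vol, _ = random_case(rng)
        cmap = classify_tissues(vol, np.zeros(vol.shape, bool))
        assert not cmap.labels.any()

    def test_labels_only_inside_roi(self, rng):
        vol, roi = random_case(rng)
        cmap = classify_tissues(vol, roi)
        assert not cmap.labels[~roi].any()


class TestAverageCT:
    def test_two_point_mean(self):
        hu = np.array([[[100.0, 120.0, -50.0]]])
        vol = HUVolume(hu)
        cmap = classify_tissues(vol, np.ones_like(hu, bool))
        assert average_ct(vol, cmap, "hematoma") == pytest.approx(110.0)

    def test_single_voxel(self):
        hu = np.array([[[800.0]]])
        vol = HUVolume(hu)
        cmap = classify_tissues(vol, np.ones_like(hu, bool))
        assert average_ct(vol, cmap, "osteogenic") == 800.0

    def test_absent_tissue_is_nan(self):
        hu = np.array([[[800.0]]])
        vol = HUVolume(hu)
        cmap = classify_tissues(vol, np.ones_like(hu, bool))
        assert np.isnan(average_ct(vol, cmap, "hematoma"))

    def test_matches_voxel_loop(self, rng):
        vol, roi = random_case(rng)
        cmap = classify_tissues(vol, roi)
        for lab, name in TISSUE_NAMES.items():
            got = average_ct(vol, cmap, name)
            expect = oracle_avg_ct(vol.data, cmap.labels, lab)
            assert got == expect or (np.isnan(got) and np.isnan(expect))


class TestIndices:
    def test_single_slice_hand_counts(self):
        """Counts (10, 10, 40, 40) give BS/TS = (10, 10, 40, 40)% summing to 100."""
        labels = np.zeros((1, 10, 10), dtype=np.uint8)
        flat = labels.ravel()
        flat[:10] = 1
        flat[10:20] = 2
        flat[20:60] = 3
        flat[60:100] = 4
        from fxcallus.morphometry import TissueClassMap

        recs = {r["tissue"]: r for r in area_volume_indices(TissueClassMap(labels, 0.01))}
        shares = [recs[TISSUE_NAMES[lab]]["bs_ts_pct"] for lab in (1, 2, 3, 4)]
        assert shares == pytest.approx([10, 10, 40, 40])
        assert sum(shares) == pytest.approx(100.0, abs=1e-9)

    def test_unit_arithmetic(self):
        """50 px/slice on 2 slices at 10 um: BS = 5e-3 mm2, BS/TV = 12.5 /mm."""
        labels = np.zeros((2, 20, 20), dtype=np.uint8)
        labels[0].ravel()[:50] = 4
        labels[1].ravel()[:50] = 4
        labels[0].ravel()[50:200] = 1  # pad to 400 total classified voxels
        labels[1].ravel()[50:200] = 1
        from fxcallus.morphometry import TissueClassMap

        recs = {r["tissue"]: r for r in area_volume_indices(TissueClassMap(labels, 0.01))}
        osteo = recs["osteogenic"]
        assert osteo["bs_mm2"] == pytest.approx(50 * 1e-4)
        assert osteo["tv_mm3"] == pytest.approx(400 * 1e-6)
        assert osteo["bs_tv_per_mm"] == pytest.approx(12.5)

    def test_uniform_single_tissue(self):
        labels = np.full((2, 4, 4), 3, dtype=np.uint8)
        from fxcallus.morphometry import TissueClassMap

        recs = {r["tissue"]: r for r in area_volume_indices(TissueClassMap(labels, 0.01))}
        assert recs["mineralized_cartilage"]["bv_tv_pct"] == pytest.approx(100.0)
        assert recs["hematoma"]["bv_tv_pct"] == 0.0

    def test_oracle_equivalence_random_volumes(self, rng):
        """Every index equals the naive triple-loop oracle exactly."""
        for _ in range(10):
            vol, roi = random_case(rng)
            cmap = classify_tissues(vol, roi)
            expect = oracle_indices(cmap.labels, 0.01)
            got = {r["tissue"]: r for r in area_volume_indices(cmap)}
            for name in TISSUE_LABELS:
                for key, val in expect[name].items():
                    assert got[name][key] == val or (np.isnan(val) and np.isnan(got[name][key]))

    def test_ratio_sums(self, rng):
        for _ in range(10):
            vol, roi = random_case(rng)
            recs = area_volume_indices(classify_tissues(vol, roi))
            if recs[0]["tv_mm3"] > 0:
                assert sum(r["bs_ts_pct"] for r in recs) == pytest.approx(100.0, abs=1e-9)
                assert sum(r["bv_tv_pct"] for r in recs) == pytest.approx(100.0, abs=1e-9)

    def test_scale_covariance(self, rng):
        """Doubling voxel size leaves fractions unchanged and halves BS/TV."""
        vol, roi = random_case(rng)
        cmap = classify_tissues(vol, roi)
        r1 = {r["tissue"]: r for r in area_volume_indices(cmap, voxel_size_mm=0.01)}
        r2 = {r["tissue"]: r for r in area_volume_indices(cmap, voxel_size_mm=0.02)}
        for name in TISSUE_LABELS:
            assert r2[name]["bs_ts_pct"] == pytest.approx(r1[name]["bs_ts_pct"], abs=1e-12)
            assert r2[name]["bv_tv_pct"] == pytest.approx(r1[name]["bv_tv_pct"], abs=1e-12)
            if r1[name]["bs_tv_per_mm"] > 0:
                assert r2[name]["bs_tv_per_mm"] == pytest.approx(r1[name]["bs_tv_per_mm"] / 2)


class TestBatch:
    def test_row_count_and_identity(self, tmp_path):
        from fxcallus.phantom import make_dataset

        manifest = make_dataset(2, days=(7, 14), out_dir=tmp_path / "ds", seed=0)
        frame = batch_morphometry(manifest)
        assert len(frame) == 4 * 2 * 4  # subjects x days x tissues
        assert set(frame["mask_source"]) == {"annotation"}

    def test_predicted_equals_annotation_when_masks_match(self, small_phantom):
        _, vol, roi, _ = small_phantom
        recs_a = morphometry_for_volume(vol, roi, "s1", "F", 14, mask_source="annotation")
        recs_b = morphometry_for_volume(vol, roi, "s1", "F", 14, mask_source="predicted")
        for a, b in zip(recs_a, recs_b):
            assert a.bs_ts_pct == b.bs_ts_pct and a.avg_ct_hu == b.avg_ct_hu
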