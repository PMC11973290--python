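"""Phantom generator: window fidelity, composition recovery, healing contrast."""

import numpy as np
import pandas as pd
import pytest

from fxcallus.morphometry import TISSUE_LABELS, area_volume_indices, classify_tissues
from fxcallus.phantom import (
    DAYS,
    DEFAULT_COMPOSITION,
    FEATURE_NAMES,
    FEATURE_STATS,
    CompositionEntry,
    PhantomConfig,
    TrainingSample,
    derive_aux_masks,
    make_dataset,
    make_phantom,
    phantom_training_samples,
    sample_feature_table,
)


class TestMakePhantom:
    def test_zero_noise_roundtrip_exact(self, small_phantom):
        """At zero noise, HU-window classification reproduces the truth map."""
        _, vol, roi, truth = small_phantom
        cmap = classify_tissues(vol, roi)
        assert np.array_equal(cmap.labels, truth.labels)

    def test_determinism(self):
        cfg = PhantomConfig(group="F+S", day=21, noise_sd_hu=15.0, seed=11)
        v1, r1, t1 = make_phantom(cfg)
        v2, r2, t2 = make_phantom(cfg)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(r1, r2) and np.array_equal(t1.labels, t2.labels)

    def test_background_and_shell_outside_windows(self, small_phantom):
        _, vol, roi, _ = small_phantom
        outside = vol.data[~roi]
        assert np.all((outside < 0) | (outside > 1000))

    def test_composition_recovery(self):
        """Morphometry on 20-seed batches recovers the configured fractions
        within 2 percentage points."""
        for group, day in (("F", 14), ("F+S", 35)):
            target = DEFAULT_COMPOSITION[(group, day)].fractions
            shares = {t: [] for t in TISSUE_LABELS}
            for seed in range(20):
                cfg = PhantomConfig(group=group, day=day, shape=(4, 64, 64), seed=seed)
                _, _, truth = make_phantom(cfg)
                recs = {r["tissue"]: r for r in area_volume_indices(truth)}
                for t in TISSUE_LABELS:
                    shares[t].append(recs[t]["bv_tv_pct"])
            for t in TISSUE_LABELS:
                assert np.mean(shares[t]) == pytest.approx(100 * target[t], abs=2.0)

    def test_day35_group_contrast(self):
        """Mean in-ROI osteogenic fraction at day 35 is strictly higher in the
        healed (F) group than the non-union (F+S) group over 20 seeds."""
        fractions = {"F": [], "F+S": []}
        for group in fractions:
            for seed in range(20):
                cfg = PhantomConfig(group=group, day=35, shape=(4, 64, 64), seed=seed)
                _, roi, truth = make_phantom(cfg)
                fractions[group].append((truth.labels == 4).sum() / roi.sum())
        assert np.mean(fractions["F"]) > np.mean(fractions["F+S"])

    def test_f_osteogenic_fraction_grows_over_days(self):
        """The healing trajectory rises through the repair phase (days 1-21)
        and ends far above baseline; the reference trajectory itself dips at
        day 28, so strict monotony is only required up to day 21."""
        vals = []
        for day in DAYS:
            _, roi, truth = make_phantom(PhantomConfig(group="F", day=day, seed=0))
            vals.append((truth.labels == 4).sum() / roi.sum())
        assert all(b > a for a, b in zip(vals[:4], vals[1:4]))
        assert vals[-1] > 2 * vals[0]

    def test_bad_fractions_rejected(self):
        comp = CompositionEntry(
            fractions={"hematoma": 0.5, "cartilage": 0.5, "mineralized_cartilage": 0.5, "osteogenic": 0.5},
            gap_fraction=0.1,
            hu_mean=DEFAULT_COMPOSITION[("F", 14)].hu_mean,
            hu_sd=DEFAULT_COMPOSITION[("F", 14)].hu_sd,
        )
        table = dict(DEFAULT_COMPOSITION)
        table[("F", 14)] = comp
        with pytest.raises(ValueError, match="sum"):
            make_phantom(PhantomConfig(group="F", day=14, composition_table=table))

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_phantom(PhantomConfig(shape=(2, 6, 6), voxel_size_mm=0.2))
        with pytest.raises(ValueError, match="field of view"):
            PhantomConfig(shape=(2, 16, 16), voxel_size_mm=0.04)


class TestAuxMasks:
    def test_constant_image_gives_zero_maps(self):
        roi = np.zeros((16, 16), bool)
        roi[4:10, 4:10] = True
        edge, m_n, m_t = derive_aux_masks(np.full((16, 16), 7.0), roi)
        assert not m_n.any() and not m_t.any()
        assert edge.any()

    def test_square_edge_matches_brute_force_perimeter(self):
        roi = np.zeros((20, 20), bool)
        roi[5:12, 6:15] = True  # 7 x 9 square
        edge, _, _ = derive_aux_masks(np.zeros((20, 20)), roi)
        perimeter = sum(
            1
            for r in range(20)
            for c in range(20)
            if roi[r, c]
            and any(
                not (0 <= r + dr < 20 and 0 <= c + dc < 20 and roi[r + dr, c + dc])
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            )
        )
        assert edge.sum() == perimeter == 2 * 7 + 2 * 9 - 4

    def test_noise_map_grows_with_sigma(self, rng):
        """Mean raw residual magnitude increases monotonically with noise level."""
        roi = np.zeros((32, 32), bool)
        roi[8:24, 8:24] = True
        clean = np.full((32, 32), 100.0)
        means = []
        for sigma in (0.0, 5.0, 10.0, 20.0):
            vals = []
            for seed in range(10):
                img = clean + np.random.default_rng(seed).normal(0, sigma, clean.shape)
                _, m_n, _ = derive_aux_masks(img, roi, normalize=False)
                vals.append(np.abs(m_n).mean())
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_normalized_maps_in_unit_range(self, small_phantom):
        _, vol, roi, _ = small_phantom
        _, m_n, m_t = derive_aux_masks(vol.data[1], roi[1])
        assert 0.0 <= m_n.min() and m_n.max() <= 1.0
        assert 0.0 <= m_t.min() and m_t.max() <= 1.0

    def test_empty_roi_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="empty ROI"):
            edge, m_n, m_t = derive_aux_masks(np.ones((8, 8)), np.zeros((8, 8), bool))
        assert not edge.any() and not m_n.any() and not m_t.any()

    def test_training_sample_shape_contract(self):
        with pytest.raises(ValueError):
            TrainingSample(
                image=np.zeros((8, 8)), roi=np.zeros((8, 8), bool),
                edge_gt=np.zeros((4, 4), bool), noise_gt=np.zeros((8, 8)),
                texture_gt=np.zeros((8, 8)),
            )


class TestFeatureTable:
    def test_day14_hematoma_mean_recovers_reference(self):
        """n=1000 draws of F day-14 hematoma CT average 103 within 3 sd/sqrt(n)."""
        frame = sample_feature_table("F", 14, n=1000, seed=0)
        mean, sd = FEATURE_STATS[("F", 14)]["avg_ct_hematoma"]
        assert frame["avg_ct_hematoma"].mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(1000))

    def test_degenerate_sd_gives_constant_rows(self):
        table = {("F", 14): {name: (5.0, 0.0) for name in FEATURE_NAMES}}
        frame = sample_feature_table("F", 14, n=10, seed=0, table=table)
        assert (frame[list(FEATURE_NAMES)] == 5.0).all().all()

    def test_seed_determinism(self):
        a = sample_feature_table("F+S", 7, n=20, seed=3)
        b = sample_feature_table("F+S", 7, n=20, seed=3)
        c = sample_feature_table("F+S", 7, n=20, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert not a[list(FEATURE_NAMES)].equals(c[list(FEATURE_NAMES)])

    def test_physical_bounds_respected(self):
        frame = sample_feature_table("F+S", 14, n=500, seed=1)
        assert frame["avg_ct_cartilage"].between(0, 1000).all()
        assert frame["bs_ts_hematoma"].between(0, 100).all()
        assert (frame["bs_tv_osteogenic"] >= 0).all()

    def test_missing_group_day_errors(self):
        with pytest.raises(ValueError, match="no feature statistics"):
            sample_feature_table("F", 3, n=5)


class TestMakeDataset:
    def test_counts_and_splits(self, tmp_path):
        manifest = make_dataset(6, days=DAYS, out_dir=tmp_path / "ds", seed=0)
        assert len(manifest) == 12 * 6
        assert manifest.split_counts() == {"train": 9, "val": 1, "test": 2}
        # subject-disjoint splits
        splits = [set(manifest.subjects(s)) for s in ("train", "val", "test")]
        assert not (splits[0] & splits[1]) and not (splits[0] & splits[2])

    def test_single_day_restriction(self, tmp_path):
        manifest = make_dataset(2, days=(14,), out_dir=tmp_path / "ds", seed=0)
        assert {e.day for e in manifest.entries} == {14}

    def test_collision_without_overwrite(self, tmp_path):
        make_dataset(1, days=(7,), out_dir=tmp_path / "ds", seed=0)
        with pytest.raises(FileExistsError):
            make_dataset(1, days=(7,), out_dir=tmp_path / "ds", seed=0)
        make_dataset(1, days=(7,), out_dir=tmp_path / "ds", seed=0, overwrite=True)

    def test_written_volumes_read_back_in_hu(self, tmp_path):
        """The on-disk calibration restores negative-HU soft tissue."""
        from fxcallus.io import load_dataset_calibration, load_manifest, read_stack

        make_dataset(1, days=(7,), out_dir=tmp_path / "ds", seed=0)
        manifest = load_manifest(tmp_path / "ds" / "manifest.csv")
        cal, vox = load_dataset_calibration(manifest.root)
        vol = read_stack(manifest.resolve(manifest.entries[0].image_path), cal, vox)
        assert vol.data.min() < 0 and vol.data.max() > 1000

    def test_phantom_training_samples_cover_lesion_slices(self):
        cfg = PhantomConfig(shape=(4, 64, 64), seed=2)
        samples = phantom_training_samples(cfg)
        assert len(samples) == 4
        for s in samples:
            assert s.roi.any() and s.image.shape == (64, 64)
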