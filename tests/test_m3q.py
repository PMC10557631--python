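"""Quantitative MRI pipeline: normalization, lesion masks, T1 partition,
voxel rims, PD-T1 summaries, ratio maps, lesion dating, tract load."""

import numpy as np
import pandas as pd
import pytest

from lesionmap import m3q

from conftest import pre_and_next_scan


def _flat_atlas(shape=(20, 20, 1), gm_rows=slice(0, 5)):
    atlas = np.full(shape, m3q.FIRST_WM_LABEL, dtype=int)
    atlas[gm_rows] = m3q.CORTICAL_GM
    return atlas


class TestNormalizePD:
    def test_cortical_gm_median_is_one(self):
        rng = np.random.default_rng(0)
        atlas = _flat_atlas()
        vol = rng.gamma(5, 100, size=atlas.shape)
        out = m3q.normalize_pd(vol, atlas)
        assert np.median(out[atlas == m3q.CORTICAL_GM]) == pytest.approx(1.0)

    def test_global_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        atlas = _flat_atlas()
        vol = rng.gamma(5, 100, size=atlas.shape)
        assert np.allclose(m3q.normalize_pd(vol, atlas),
                           m3q.normalize_pd(vol * 3.7, atlas))

    def test_uniform_volume_all_ones(self):
        atlas = _flat_atlas()
        assert np.allclose(m3q.normalize_pd(np.full(atlas.shape, 42.0), atlas), 1.0)

    def test_missing_cortical_gm_rejected(self):
        atlas = np.full((4, 4, 1), m3q.FIRST_WM_LABEL)
        with pytest.raises(ValueError):
            m3q.normalize_pd(np.ones(atlas.shape), atlas)


class TestLesionMask:
    def test_identical_volumes_empty_mask(self):
        vol = np.random.default_rng(2).random((10, 10, 2))
        assert not m3q.lesion_mask(vol, vol).any()

    def test_decreasing_voxels_never_in_mask(self):
        base = np.ones((5, 5, 1))
        term = base - 0.5
        assert not m3q.lesion_mask(base, term).any()

    def test_planted_increase_recovered_exactly(self):
        base = np.ones((10, 10, 1)) * 0.7
        term = base.copy()
        region = np.zeros_like(base, dtype=bool)
        region[3:6, 3:6] = True
        term[region] *= 1.5
        assert np.array_equal(m3q.lesion_mask(base, term, 0.2), region)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m3q.lesion_mask(np.ones((3, 3, 1)), np.ones((4, 4, 1)))

    def test_synthetic_series_recovery_exact(self, mri_series):
        s = mri_series
        base = m3q.normalize_pd(s.pd_volumes[0], s.atlas)
        term = m3q.normalize_pd(s.pd_volumes[-1], s.atlas)
        detected = m3q.lesion_mask(base, term, 0.2)
        assert np.array_equal(detected, s.pd_elevated_masks[-1])


class TestPartitionByT1:
    def test_hot_lesion_has_no_edge(self):
        lesion = np.ones((4, 4, 1), dtype=bool)
        core, edge = m3q.partition_by_t1(lesion, np.full(lesion.shape, 2000.0))
        assert core.all() and not edge.any()

    def test_cool_lesion_has_no_core(self):
        lesion = np.ones((4, 4, 1), dtype=bool)
        core, edge = m3q.partition_by_t1(lesion, np.full(lesion.shape, 900.0))
        assert edge.all() and not core.any()

    def test_exact_cutoff_goes_to_edge(self):
        lesion = np.ones((1, 1, 1), dtype=bool)
        core, edge = m3q.partition_by_t1(lesion, np.full(lesion.shape, 1250.0))
        assert not core.any() and edge.all()

    def test_partition_exhaustive_and_disjoint(self, mri_series):
        s = mri_series
        lesion = s.lesion_masks[-1]
        core, edge = m3q.partition_by_t1(lesion, s.t1_volumes[-1])
        assert not (core & edge).any()
        assert np.array_equal(core | edge, lesion)
        # planted core T1 of 2000 ms lands above the cutoff
        assert core.sum() > 0.9 * lesion.sum()


class TestVoxelRims:
    def test_chebyshev_rings_of_8k(self):
        core = np.zeros((21, 21, 1), dtype=bool)
        core[10, 10, 0] = True
        wm = np.ones_like(core)
        field = m3q.voxel_rims(core, wm, n=5)
        for k in range(1, 6):
            assert (field == k).sum() == 8 * k
            rr, cc, _ = np.nonzero(field == k)
            cheb = np.maximum(np.abs(rr - 10), np.abs(cc - 10))
            assert (cheb == k).all()

    def test_rim5_outer_boundary_750um(self):
        core = np.zeros((21, 21, 1), dtype=bool)
        core[10, 10, 0] = True
        field = m3q.voxel_rims(core, np.ones_like(core), n=5)
        rr, cc, _ = np.nonzero(field == 5)
        cheb_mm = np.maximum(np.abs(rr - 10), np.abs(cc - 10)) * 0.15
        assert cheb_mm.max() * 1000 == pytest.approx(750.0)
        assert m3q.rim_outer_distance_um(5, 0.15) == 750.0

    def test_rims_confined_to_wm(self):
        core = np.zeros((15, 15, 1), dtype=bool)
        core[7, 7, 0] = True
        wm = np.zeros_like(core)
        wm[:, :9] = True
        field = m3q.voxel_rims(core, wm, n=5)
        assert not ((field > 0) & ~wm).any()

    def test_empty_core_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            field = m3q.voxel_rims(np.zeros((5, 5, 1), dtype=bool),
                                   np.ones((5, 5, 1), dtype=bool))
        assert (field == m3q.RIM_OUTSIDE).all()

    def test_four_connectivity_gives_diamond_rings(self):
        core = np.zeros((15, 15, 1), dtype=bool)
        core[7, 7, 0] = True
        field = m3q.voxel_rims(core, np.ones_like(core), n=3, connectivity=4)
        rr, cc, _ = np.nonzero(field == 2)
        manhattan = np.abs(rr - 7) + np.abs(cc - 7)
        assert (manhattan == 2).all() and len(rr) == 8

    def test_pd_gradient_monotone_toward_core(self):
        """When PD decays with distance from the core, per-rim mean PD is
        monotone non-increasing outward."""
        core = np.zeros((31, 31, 1), dtype=bool)
        core[15, 15, 0] = True
        wm = np.ones_like(core)
        field = m3q.voxel_rims(core, wm, n=5)
        rr, cc = np.meshgrid(np.arange(31), np.arange(31), indexing="ij")
        pd_vol = (2.0 - 0.1 * np.maximum(np.abs(rr - 15), np.abs(cc - 15)))[..., None]
        means = [pd_vol[field == k].mean() for k in range(1, 6)]
        assert (np.diff(means) <= 0).all()


class TestPDT1Summary:
    def test_histogram_counts_sum_to_region_size(self, mri_series):
        s = mri_series
        wm = m3q.wm_mask_from_atlas(s.atlas)
        norm = m3q.normalize_pd(s.pd_volumes[0], s.atlas)
        out = m3q.pdt1_summary(norm, s.t1_volumes[0], wm)
        assert out["hist"].sum() == wm.sum() == out["n_voxels"]

    def test_single_voxel_region(self):
        region = np.zeros((3, 3, 1), dtype=bool)
        region[1, 1, 0] = True
        out = m3q.pdt1_summary(np.ones((3, 3, 1)), np.full((3, 3, 1), 900.0),
                               region, bins=5)
        assert (out["hist"] > 0).sum() == 1

    def test_healthy_wm_t1_tail_matches_configuration(self, mri_series):
        """WM T1 is drawn around 900 +- 40 ms, so essentially no healthy-WM
        voxel crosses the 1250 ms cutoff (the configured tail is ~1e-18)."""
        s = mri_series
        wm = m3q.wm_mask_from_atlas(s.atlas) & ~s.lesion_masks[-1]
        norm = m3q.normalize_pd(s.pd_volumes[-1], s.atlas)
        out = m3q.pdt1_summary(norm, s.t1_volumes[-1], wm)
        assert out["frac_t1_above_cutoff"] == pytest.approx(0.0, abs=1e-3)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            m3q.pdt1_summary(np.ones((2, 2, 1)), np.ones((2, 2, 1)),
                             np.zeros((2, 2, 1), dtype=bool))


class TestPDOverT1:
    def test_constant_inputs_constant_ratio(self):
        ratio = m3q.pd_over_t1_ratio(np.full((4, 4, 1), 0.8),
                                     np.full((4, 4, 1), 1000.0))
        assert np.allclose(ratio, 0.0008)

    def test_zero_t1_masked_not_infinite(self):
        t1 = np.array([[[0.0], [1000.0]]])
        ratio = m3q.pd_over_t1_ratio(np.ones_like(t1), t1)
        assert np.isnan(ratio[0, 0, 0]) and np.isfinite(ratio[0, 1, 0])

    def test_invariant_to_raw_pd_rescaling(self):
        rng = np.random.default_rng(4)
        atlas = _flat_atlas()
        raw = rng.gamma(5, 100, size=atlas.shape)
        t1 = rng.normal(1000, 50, size=atlas.shape)
        r1 = m3q.pd_over_t1_ratio(m3q.normalize_pd(raw, atlas), t1)
        r2 = m3q.pd_over_t1_ratio(m3q.normalize_pd(raw * 9.1, atlas), t1)
        assert np.allclose(r1, r2)


class TestEarlyWarning:
    def test_pre_lesion_ratio_ranks_future_lesion_voxels(self, mri_series):
        s = mri_series
        pre, nxt = pre_and_next_scan(s)
        norm = m3q.normalize_pd(s.pd_volumes[pre], s.atlas)
        ratio = m3q.pd_over_t1_ratio(norm, s.t1_volumes[pre])
        wm = m3q.wm_mask_from_atlas(s.atlas)
        future = s.lesion_masks[nxt] & wm
        assert s.lesion_masks[pre].sum() == 0          # nothing on T1 yet
        threshold = np.quantile(ratio[wm], 0.9)
        capture = (ratio[future] > threshold).mean()
        assert capture >= 0.8


class TestLesionAge:
    def test_gap_brackets_maximum_age(self):
        recs = m3q.lesion_age_intervals({"L1": [False, True]}, [30, 37])
        (rec,) = recs
        assert rec.detected_day == 37 and rec.max_age_days == 7
        assert not rec.left_censored

    def test_baseline_presence_left_censored(self):
        (rec,) = m3q.lesion_age_intervals({"L1": [True, True]}, [0, 7])
        assert rec.left_censored and np.isinf(rec.max_age_days)

    def test_never_present_gives_no_records(self):
        assert m3q.lesion_age_intervals({"L1": [False, False]}, [0, 7]) == []

    def test_resurrection_yields_flagged_episodes(self):
        recs = m3q.lesion_age_intervals({"L1": [True, False, True]}, [0, 7, 14])
        assert len(recs) == 2
        assert all(r.resurrected for r in recs)

    def test_non_monotone_days_rejected(self):
        with pytest.raises(ValueError):
            m3q.lesion_age_intervals({"L1": [True, True]}, [7, 7])


class TestTractLoad:
    def test_no_lesions_all_zero(self):
        atlas = _flat_atlas()
        masks = [np.zeros(atlas.shape, dtype=bool) for _ in range(5)]
        hit_pct, table = m3q.tract_lesion_load(masks, atlas)
        assert (hit_pct == 0).all()
        assert (table["mean_voxel_pct"] == 0).all()

    def test_one_of_five_subjects_gives_twenty_percent(self):
        atlas = _flat_atlas()
        tract = atlas == m3q.FIRST_WM_LABEL
        masks = [tract.copy()] + [np.zeros(atlas.shape, dtype=bool)] * 4
        hit_pct, table = m3q.tract_lesion_load(masks, atlas)
        assert np.allclose(hit_pct[tract], 20.0)
        assert table["lesioned_voxel_fraction"].iloc[0] == 1.0

    def test_matches_naive_per_voxel_tally(self):
        rng = np.random.default_rng(5)
        atlas = _flat_atlas((10, 10, 1))
        masks = [rng.random(atlas.shape) > 0.8 for _ in range(4)]
        hit_pct, _ = m3q.tract_lesion_load(masks, atlas)
        for idx in np.ndindex(atlas.shape):
            expected = 100.0 * sum(m[idx] for m in masks) / 4
            assert hit_pct[idx] == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        atlas = _flat_atlas((6, 6, 1))
        with pytest.raises(ValueError):
            m3q.tract_lesion_load([np.zeros((5, 5, 1), dtype=bool)], atlas)
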