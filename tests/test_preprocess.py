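"""Column correction, tissue masking, tiling and QC rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octliver import phantom as ph
from octliver.exceptions import ParameterError
from octliver.preprocess import (
    PreprocParams,
    TissueMask,
    binarize,
    crop_tiles,
    preprocess_cscan,
    qc_bscan,
    qc_cscan,
    remove_reflection_columns,
    tissue_mask,
    tiles_to_manifest,
)
from octliver.volume_io import BScanImage, scale_to_8bit


def bscan(pixels, idx=0):
    return BScanImage(pixels=np.asarray(pixels, dtype=np.uint8), scan_id="s", bscan_index=idx)


class TestColumnRemoval:
    def test_uniform_image_loses_no_columns(self, default_params):
        out, removed = remove_reflection_columns(bscan(np.full((30, 30), 40)), default_params)
        assert removed == []
        assert out.pixels.shape == (30, 30)

    def test_planted_bright_columns_removed_exactly(self, default_params):
        img = np.full((100, 100), 10, dtype=np.uint8)
        img[:, 5] = 255
        img[:, 17] = 255
        # independent oracle: recompute the rule by brute force
        mean, std = img.mean(), img.std()
        expected = [c for c in range(100) if img[:, c].mean() > mean + default_params.artifact_k * std]
        assert expected == [5, 17]
        out, removed = remove_reflection_columns(bscan(img), default_params)
        assert removed == [5, 17]
        assert out.pixels.shape == (100, 98)

    def test_phantom_artifacts_recovered_from_ground_truth(self, tumor_scan, default_params):
        raw, gt = tumor_scan
        total = 0
        for img in scale_to_8bit(raw):
            planted = sorted(c for b, c in gt.artifact_columns if b == img.bscan_index)
            _, removed = remove_reflection_columns(img, default_params)
            assert removed == planted
            total += len(planted)
        assert total > 0

    def test_second_pass_removes_no_already_removed_artifact(self, tumor_scan, default_params):
        raw, gt = tumor_scan
        img = scale_to_8bit(raw)[0]
        corrected, removed = remove_reflection_columns(img, default_params)
        # map surviving columns back to original indices
        survivors = [c for c in range(img.pixels.shape[1]) if c not in removed]
        _, removed2 = remove_reflection_columns(corrected, default_params)
        planted = {c for b, c in gt.artifact_columns if b == 0}
        assert planted.isdisjoint({survivors[c] for c in removed2})


class TestTissueMask:
    def test_all_zero_image_gives_empty_mask(self, default_params):
        m = tissue_mask(bscan(np.zeros((40, 40))), default_params)
        assert not m.mask.any()

    @pytest.mark.parametrize("value", [20, 21])
    def test_isolated_pixel_vanishes(self, value, default_params):
        # value 20 is below the binarization threshold; value 21 survives the
        # threshold but a lone pixel is erased by the 5x5 median filter
        img = np.zeros((40, 40), dtype=np.uint8)
        img[20, 20] = value
        m = tissue_mask(bscan(img), default_params)
        assert not m.mask.any()

    def test_solid_band_is_recovered_with_filled_holes(self, default_params):
        img = np.zeros((100, 80), dtype=np.uint8)
        img[10:60, :] = 200
        img[30:34, 30:34] = 0  # enclosed hole -> filled
        m = tissue_mask(bscan(img), default_params).mask
        assert m[20:50, 10:70].all()
        assert m[30:34, 30:34].all()
        assert not m[70:, :].any()
        assert not m[:5, :].any()

    def test_phantom_mask_matches_ground_truth_band(self, tumor_scan, default_params):
        raw, gt = tumor_scan
        img = scale_to_8bit(raw)[1]
        corrected, removed = remove_reflection_columns(img, default_params)
        pred = tissue_mask(corrected, default_params).mask.astype(bool)
        truth = np.delete(gt.tissue_mask[1].astype(bool), removed, axis=1)
        iou = (pred & truth).sum() / (pred | truth).sum()
        assert iou >= 0.90

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 254))
    def test_raising_threshold_never_grows_foreground(self, seed, t):
        img = np.random.default_rng(seed).integers(0, 256, (20, 20), dtype=np.uint8)
        lower, higher = binarize(img, t), binarize(img, t + 1)
        assert np.all(higher <= lower)


class TestCropTiles:
    def test_exact_fit_single_tile(self):
        p = PreprocParams(tile_size_px=299, tile_stride_px=299, min_tissue_fraction=1.0)
        img = bscan(np.full((299, 299), 99))
        tiles = crop_tiles(img, TissueMask(np.ones((299, 299))), p, "healthy")
        assert len(tiles) == 1
        assert (tiles[0].row_offset, tiles[0].col_offset) == (0, 0)

    def test_grid_origins_clip_to_image_edge(self):
        p = PreprocParams(tile_size_px=299, tile_stride_px=150, min_tissue_fraction=1.0)
        img = bscan(np.full((299, 598), 99))
        tiles = crop_tiles(img, TissueMask(np.ones((299, 598))), p, "tumor")
        assert sorted(t.col_offset for t in tiles) == [0, 150, 299]
        assert all(t.row_offset == 0 for t in tiles)

    def test_empty_mask_and_small_image_yield_no_tiles(self, default_params):
        img = bscan(np.full((400, 400), 99))
        assert crop_tiles(img, TissueMask(np.zeros((400, 400))), default_params, "tumor") == []
        small = bscan(np.full((100, 400), 99))
        assert crop_tiles(small, TissueMask(np.ones((100, 400))), default_params, "tumor") == []

    def test_masked_out_pixels_are_zeroed(self):
        p = PreprocParams(tile_size_px=10, tile_stride_px=10, min_tissue_fraction=0.5)
        img = bscan(np.full((10, 10), 77))
        mask = np.ones((10, 10))
        mask[:, 7:] = 0
        tiles = crop_tiles(img, TissueMask(mask), p, "healthy")
        assert len(tiles) == 1
        assert np.all(tiles[0].pixels[:, 7:] == 0)
        assert np.all(tiles[0].pixels[:, :7] == 77)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 8))
    def test_every_coverable_positive_pixel_lands_in_a_tile(self, seed, stride):
        ts = 8
        p = PreprocParams(tile_size_px=ts, tile_stride_px=stride, min_tissue_fraction=0.0)
        rng = np.random.default_rng(seed)
        mask = (rng.uniform(size=(30, 25)) < 0.3).astype(np.uint8)
        img = bscan(np.full((30, 25), 50))
        tiles = crop_tiles(img, TissueMask(mask), p, "healthy")
        covered = np.zeros_like(mask, dtype=bool)
        for t in tiles:
            covered[t.row_offset : t.row_offset + ts, t.col_offset : t.col_offset + ts] = True
        assert np.all(covered[mask.astype(bool)])


class TestQCRules:
    @pytest.mark.parametrize(
        "ow,cw,n_tiles,flagged,reason_part",
        [
            (1024, 682, 5, True, "cropped"),   # 342/1024 >= 1/3
            (1024, 1000, 5, False, ""),
            (1024, 1024, 0, True, "no tiles"),
        ],
    )
    def test_bscan_flagging(self, ow, cw, n_tiles, flagged, reason_part, default_params):
        got_flag, reason = qc_bscan(ow, cw, n_tiles, default_params)
        assert got_flag is flagged
        assert reason_part in reason

    @pytest.mark.parametrize(
        "n,flagged,excluded",
        [(9, 3, True), (9, 2, False), (9, 0, False), (3, 1, True)],
    )
    def test_cscan_exclusion_threshold_is_inclusive(self, n, flagged, excluded, default_params):
        flags = [True] * flagged + [False] * (n - flagged)
        frac, got = qc_cscan(flags, default_params)
        assert got is excluded
        assert frac == pytest.approx(flagged / n)


class TestPipeline:
    def test_pipeline_is_deterministic_and_tiles_valid(self, tumor_scan, default_params):
        raw, _ = tumor_scan
        tiles1, report1 = preprocess_cscan(raw, default_params)
        tiles2, _ = preprocess_cscan(raw, default_params)
        assert len(tiles1) == len(tiles2) > 0
        for t1, t2 in zip(tiles1, tiles2):
            assert np.array_equal(t1.pixels, t2.pixels)
            assert t1.pixels.shape == (299, 299)
            assert t1.label == "tumor"
            assert t1.scan_id == raw.meta.scan_id
        assert len(report1.bscans) == raw.meta.n_bscans
        assert not report1.excluded

    def test_violator_cscan_is_excluded_with_empty_tiles(self):
        params = ph.tumor_params(n_bscans=3, artifact_col_rate=160.0, seed=31)
        raw, _ = ph.generate_cscan(params, "tumor")
        tiles, report = preprocess_cscan(raw, PreprocParams())
        assert report.excluded
        assert tiles == []
        assert report.flagged_fraction >= 1 / 3

    def test_report_accounts_for_every_bscan(self, healthy_scan, default_params):
        raw, _ = healthy_scan
        tiles, report = preprocess_cscan(raw, default_params)
        assert sorted(r.bscan_index for r in report.bscans) == list(range(raw.meta.n_bscans))
        retained_from = {t.bscan_index for t in tiles}
        flagged = {r.bscan_index for r in report.bscans if r.flagged}
        assert retained_from.isdisjoint(flagged)
        kept_with_tiles = {r.bscan_index for r in report.bscans if not r.flagged and r.n_tiles}
        assert retained_from == kept_with_tiles
        df = report.to_dataframe()
        assert len(df) == raw.meta.n_bscans + 1  # + summary row

    def test_manifest_has_one_row_per_tile(self, healthy_scan, default_params):
        raw, _ = healthy_scan
        tiles, _ = preprocess_cscan(raw, default_params)
        manifest = tiles_to_manifest(tiles, {raw.meta.scan_id: "patient_x"})
        assert len(manifest) == len(tiles)
        assert set(manifest["label"]) == {"healthy"}
        assert set(manifest["patient_id"]) == {"patient_x"}
        assert manifest["tile_id"].is_unique


def test_invalid_preproc_params_rejected():
    with pytest.raises(ParameterError):
        PreprocParams(tile_stride_px=0)
    with pytest.raises(ParameterError):
        PreprocParams(tile_stride_px=400, tile_size_px=299)
    with pytest.raises(ParameterError):
        PreprocParams(min_tissue_fraction=1.2)
    with pytest.raises(ParameterError):
        PreprocParams(median_size=4)
    with pytest.raises(ParameterError):
        PreprocParams(binarize_threshold=300)
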