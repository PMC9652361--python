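"""Segmentation and per-cell feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenogate.errors import SegmentationError
from phenogate.features import (
    CellSegmentation,
    SegmentationConfig,
    copi_features,
    golgi_features,
    perinuclear_roi,
    segment_cell,
    tfn_features,
)
from phenogate.stack import ImageStack
from phenogate.synth import SyntheticCellSpec, generate_cell_image


def _disk(shape, center, radius):
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _toy_segmentation(shape=(64, 64)):
    cell = _disk(shape, (32, 32), 28)
    nucleus = _disk(shape, (32, 32), 8)
    return cell, nucleus


class TestSegmentation:
    def test_noiseless_synthetic_masks_recovered_exactly(self, compact_cell):
        stack, truth = compact_cell
        seg = segment_cell(stack)
        assert np.array_equal(seg.cell_mask, truth.cell_mask)
        assert np.array_equal(seg.nucleus_mask, truth.nucleus_mask)
        assert np.array_equal(seg.organelle_masks["golgi"], truth.golgi_mask)

    def test_all_zero_marker_channel_raises_naming_the_channel(self):
        shape = (32, 32)
        stack = ImageStack({"marker": np.zeros(shape),
                            "nucleus": np.ones(shape),
                            "golgi": np.ones(shape)})
        with pytest.raises(SegmentationError, match="marker"):
            segment_cell(stack)

    def test_largest_marker_component_wins(self):
        shape = (64, 64)
        big = _disk(shape, (20, 20), 12)
        small = _disk(shape, (50, 50), 5)
        marker = 100.0 * (big | small)
        nucleus_ch = np.zeros(shape)
        nucleus_ch[big & _disk(shape, (20, 20), 4)] = 80.0
        golgi_ch = np.zeros(shape)
        stack = ImageStack({"marker": marker, "nucleus": nucleus_ch,
                            "golgi": golgi_ch})
        seg = segment_cell(stack)
        assert np.array_equal(seg.cell_mask, big)

    def test_nucleus_outside_cell_raises(self):
        shape = (64, 64)
        cell = _disk(shape, (20, 20), 10)
        stack = ImageStack({"marker": 100.0 * cell,
                            "nucleus": 80.0 * _disk(shape, (50, 50), 5),
                            "golgi": np.zeros(shape)})
        with pytest.raises(SegmentationError, match="nucleus"):
            segment_cell(stack)

    def test_masks_nest_after_segmentation(self, dispersed_cell):
        stack, _ = dispersed_cell
        seg = segment_cell(stack)
        assert not (seg.nucleus_mask & ~seg.cell_mask).any()
        for mask in seg.organelle_masks.values():
            assert not (mask & ~seg.cell_mask).any()


class TestGolgiFeatures:
    def test_area_is_pixel_count_ratio(self):
        cell, nucleus = _toy_segmentation()
        golgi = np.zeros_like(cell)
        idx = np.argwhere(cell)
        n = int(round(0.02 * cell.sum()))
        golgi[tuple(idx[:n].T)] = True
        seg = CellSegmentation(cell, nucleus, {"golgi": golgi})
        feats = golgi_features(seg, 50.0 * golgi.astype(float))
        assert feats.a == pytest.approx(100.0 * n / cell.sum(), abs=1e-12)

    def test_uniform_channel_gives_mi_one_under_cell_normalization(self):
        cell, nucleus = _toy_segmentation()
        golgi = _disk(cell.shape, (20, 40), 5) & cell
        seg = CellSegmentation(cell, nucleus, {"golgi": golgi})
        cfg = SegmentationConfig(mi_normalization="cell")
        feats = golgi_features(seg, 37.0 * cell.astype(float), cfg)
        assert feats.mi == pytest.approx(1.0, abs=1e-12)

    def test_synthetic_cell_hits_targets(self, dispersed_cell):
        """Ground-truth masks + noiseless image reproduce the (15, 0.4) target."""
        stack, truth = dispersed_cell
        seg = CellSegmentation(truth.cell_mask, truth.nucleus_mask,
                               {"golgi": truth.golgi_mask})
        feats = golgi_features(seg, stack["golgi"])
        assert feats.a == pytest.approx(truth.realized_a, abs=1e-9)
        assert feats.mi == pytest.approx(0.4, abs=1e-9)
        half_pixel_pct = 100.0 * 0.5 / truth.cell_mask.sum()
        assert feats.a == pytest.approx(15.0, abs=half_pixel_pct)

    def test_empty_golgi_mask_gives_nan_sentinel_not_zero(self):
        cell, nucleus = _toy_segmentation()
        seg = CellSegmentation(cell, nucleus, {"golgi": np.zeros_like(cell)})
        feats = golgi_features(seg, np.zeros(cell.shape))
        assert feats.a == 0.0
        assert np.isnan(feats.mi)
        assert not feats.mi_defined

    @given(scale=st.floats(min_value=0.01, max_value=100.0,
                           allow_nan=False, allow_infinity=False))
    @settings(max_examples=25, deadline=None)
    def test_a_and_mi_invariant_to_positive_rescaling_cell_mode(self, scale):
        """Cell-normalized MI and A are unchanged by channel rescaling."""
        cell, nucleus = _toy_segmentation()
        golgi = _disk(cell.shape, (20, 40), 5) & cell
        seg = CellSegmentation(cell, nucleus, {"golgi": golgi})
        chan = np.where(golgi, 90.0, 10.0) * cell
        cfg = SegmentationConfig(mi_normalization="cell")
        f1 = golgi_features(seg, chan, cfg)
        f2 = golgi_features(seg, scale * chan, cfg)
        assert f1.a == f2.a
        assert f1.mi == pytest.approx(f2.mi, rel=1e-12)


class TestCopiFeatures:
    def test_perinuclear_blob_ratio_and_flag(self):
        cell, nucleus = _toy_segmentation()
        n_copi = int(round(0.2 * nucleus.sum()))
        idx = np.argwhere(cell & ~nucleus)
        order = np.argsort(((idx - np.array([32.0, 41.0])) ** 2).sum(axis=1))
        copi = np.zeros_like(cell)
        copi[tuple(idx[order[:n_copi]].T)] = True
        seg = CellSegmentation(cell, nucleus, {"copi": copi})
        feats = copi_features(seg)
        assert feats.area_ratio == pytest.approx(0.2, abs=1e-2)
        assert feats.pn_clustered

    def test_no_copi_signal(self):
        cell, nucleus = _toy_segmentation()
        seg = CellSegmentation(cell, nucleus, {"copi": np.zeros_like(cell)})
        feats = copi_features(seg)
        assert feats.area_ratio == 0.0
        assert feats.n_components == 0
        assert not feats.pn_clustered

    def test_scattered_far_puncta_not_clustered(self):
        shape = (128, 128)
        cell = _disk(shape, (64, 64), 60)
        nucleus = _disk(shape, (64, 64), 10)
        copi = np.zeros(shape, dtype=bool)
        count = 0
        for i in range(20, 110, 18):
            for j in range(20, 110, 18):
                if np.hypot(i - 64, j - 64) > 30 and cell[i, j]:
                    copi[i, j] = True
                    count += 1
        seg = CellSegmentation(cell, nucleus, {"copi": copi})
        feats = copi_features(seg)
        assert feats.n_components == count
        assert not feats.pn_clustered


class TestTfnFeatures:
    def test_all_signal_inside_roi(self):
        cell, nucleus = _toy_segmentation()
        seg = CellSegmentation(cell, nucleus, {"tfn": np.zeros_like(cell)})
        roi = perinuclear_roi(seg, width=10)
        tfn_mask = roi.copy()
        seg = CellSegmentation(cell, nucleus, {"tfn": tfn_mask})
        feats = tfn_features(seg, 60.0 * tfn_mask.astype(float), roi)
        assert feats.pn_fraction == pytest.approx(1.0)

    def test_uniform_signal_proportional_to_roi_area(self):
        cell, nucleus = _toy_segmentation()
        tfn_mask = cell.copy()
        seg = CellSegmentation(cell, nucleus, {"tfn": tfn_mask})
        roi = np.zeros_like(cell)
        idx = np.argwhere(cell)
        n = int(round(0.1 * cell.sum()))
        roi[tuple(idx[:n].T)] = True
        feats = tfn_features(seg, 10.0 * cell.astype(float), roi)
        assert feats.pn_fraction == pytest.approx(n / cell.sum(), abs=1e-12)

    def test_empty_tfn_signal_flagged(self):
        cell, nucleus = _toy_segmentation()
        seg = CellSegmentation(cell, nucleus, {"tfn": np.zeros_like(cell)})
        feats = tfn_features(seg, np.zeros(cell.shape))
        assert feats.empty
        assert feats.pn_fraction == 0.0
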