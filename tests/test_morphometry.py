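import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ellipe
from skimage.measure import regionprops

import nepheno as ne
from nepheno.io_formats import ChannelImage, LabeledMask
from nepheno.morphometry import match_objects


def rasterized_ellipse(a, b, pad=6):
    n = int(2 * max(a, b)) + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    return ((((xx - n / 2) / a) ** 2 + ((yy - n / 2) / b) ** 2) <= 1).astype(np.int32)


class TestFormFactor:
    def test_circle_is_exactly_one(self):
        r = 50.0
        assert ne.form_factor(np.pi * r**2, 2 * np.pi * r) == pytest.approx(1.0, abs=1e-15)

    def test_square_closed_form(self):
        s = 7.0
        assert ne.form_factor(s**2, 4 * s) == pytest.approx(np.pi / 4, abs=1e-12)

    def test_two_to_one_ellipse_against_arc_length_oracle(self):
        # exact perimeter of an ellipse: P = 4 a E(m), m = 1 - (b/a)^2
        a, b = 2.0, 1.0
        P = 4 * a * ellipe(1 - (b / a) ** 2)
        expected = 4 * np.pi * (np.pi * a * b) / P**2
        assert expected == pytest.approx(0.8412, abs=5e-4)  # frozen from the oracle
        assert ne.form_factor(np.pi * a * b, P) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("A,P", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_inputs_rejected(self, A, P):
        with pytest.raises(ValueError):
            ne.form_factor(A, P)

    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4), st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, A, P, c):
        # FF(c²A, cP) = FF(A, P): the metric is dimensionless
        assert ne.form_factor(c**2 * A, c * P) == pytest.approx(
            ne.form_factor(A, P), rel=1e-9)


class TestMeasureNuclei:
    def test_rasterized_disk_form_factor_near_one(self):
        labels = rasterized_ellipse(50, 50)
        rec = ne.measure_nuclei(LabeledMask(labels))
        assert 0.95 <= rec.loc[0, "form_factor"] <= 1.05
        # perimeter estimator within 5% of 2πr
        assert rec.loc[0, "perimeter_px"] == pytest.approx(2 * np.pi * 50, rel=0.05)

    def test_uniform_channel_mean_intensity(self, clean_pair):
        dapi, _, _ = clean_pair
        mask = ne.segment_nuclei(dapi)
        flat = ChannelImage(np.full(dapi.shape, 42.0))
        rec = ne.measure_nuclei(mask, {"flat": flat})
        assert np.allclose(rec["mean_intensity_flat"], 42.0)

    def test_form_factor_decreases_with_eccentricity(self):
        area = 5000.0
        ffs = []
        for e in (0.0, 0.5, 0.8, 0.95):
            a = np.sqrt(area / np.pi / np.sqrt(1 - e**2))
            b = a * np.sqrt(1 - e**2)
            rec = ne.measure_nuclei(LabeledMask(rasterized_ellipse(a, b)))
            ffs.append(rec.loc[0, "form_factor"])
        assert all(x > y for x, y in zip(ffs, ffs[1:]))

    def test_shape_mismatch_rejected(self, clean_pair):
        dapi, _, _ = clean_pair
        mask = ne.segment_nuclei(dapi)
        with pytest.raises(ValueError):
            ne.measure_nuclei(mask, {"bad": ChannelImage(np.ones((5, 5)))})

    def test_empty_mask_gives_empty_table(self):
        rec = ne.measure_nuclei(LabeledMask(np.zeros((20, 20), dtype=np.int32)))
        assert rec.empty


class TestDetectBlebs:
    def test_identical_masks_zero_blebs(self):
        labels = rasterized_ellipse(20, 15)
        m = LabeledMask(labels)
        blebs, unmatched = ne.detect_blebs(m, m)
        assert blebs.empty and unmatched == []

    def test_planted_bleb_recovered_with_area(self, clean_pair):
        dapi, lamin, truth = clean_pair
        dm = ne.segment_nuclei(dapi, ne.SegmentationParams(min_area=100))
        lm = ne.segment_nuclei(lamin, ne.SegmentationParams(min_area=100))
        blebs, unmatched = ne.detect_blebs(dm, lm, ne.BlebParams(min_bleb_area=20))
        assert len(blebs) == 3 and unmatched == []
        for _, row in blebs.iterrows():
            bleb_lab = truth.bleb_labels[int(round(row.centroid_r)), int(round(row.centroid_c))]
            assert bleb_lab > 0
            assert row.area_px == pytest.approx(truth.bleb_areas[bleb_lab], rel=0.15)

    def test_min_area_filter_removes_small_blebs(self, clean_pair):
        dapi, lamin, _ = clean_pair
        dm = ne.segment_nuclei(dapi, ne.SegmentationParams(min_area=100))
        lm = ne.segment_nuclei(lamin, ne.SegmentationParams(min_area=100))
        blebs, _ = ne.detect_blebs(dm, lm, ne.BlebParams(min_bleb_area=1e5))
        assert blebs.empty

    def test_monotone_in_min_bleb_area(self, clean_pair):
        dapi, lamin, _ = clean_pair
        dm = ne.segment_nuclei(dapi, ne.SegmentationParams(min_area=100))
        lm = ne.segment_nuclei(lamin, ne.SegmentationParams(min_area=100))
        counts = [len(ne.detect_blebs(dm, lm, ne.BlebParams(min_bleb_area=t))[0])
                  for t in (0, 25, 50, 100, 200)]
        assert counts == sorted(counts, reverse=True)

    def test_unmatched_nucleus_flagged_not_error(self, clean_pair):
        dapi, lamin, _ = clean_pair
        dm = ne.segment_nuclei(dapi, ne.SegmentationParams(min_area=100))
        empty = LabeledMask(np.zeros_like(dm.labels))
        blebs, unmatched = ne.detect_blebs(dm, empty)
        assert blebs.empty
        assert sorted(unmatched) == sorted(dm.present_labels.tolist())
        counts = ne.bleb_counts_per_nucleus(dm, blebs, unmatched)
        assert counts["n_blebs"].isna().all()

    def test_matching_by_maximal_overlap(self):
        a = np.zeros((30, 60), dtype=np.int32)
        b = np.zeros((30, 60), dtype=np.int32)
        a[5:15, 5:15] = 1
        a[5:15, 30:40] = 2
        b[6:16, 6:16] = 7   # overlaps a:1
        b[5:15, 31:41] = 3  # overlaps a:2
        m = match_objects(LabeledMask(a), LabeledMask(b))
        assert m == {1: 7, 2: 3}


class TestSummaries:
    def test_percent_blebbing_arithmetic(self):
        assert ne.percent_blebbing([0, 0, 0]) == 0.0
        assert ne.percent_blebbing([1, 0, 2, 0, 0, 0, 0, 0, 1, 0]) == 30.0

    def test_percent_blebbing_empty_raises(self):
        with pytest.raises(ValueError):
            ne.percent_blebbing([np.nan, np.nan])

    def test_summarize_groups_per_replicate_and_pooled(self):
        rec = pd.DataFrame({
            "condition": ["wt"] * 4 + ["mut"] * 4,
            "replicate": [0, 0, 1, 1] * 2,
            "form_factor": [0.9, 0.8, 0.95, 0.85, 0.6, 0.5, 0.65, 0.55],
            "n_blebs": [0, 0, 0, 1, 1, 1, 1, 0],
        })
        summary = ne.summarize_morphometry(rec)
        pooled = summary[summary["replicate"] == "pooled"].set_index("condition")
        assert pooled.loc["wt", "percent_blebbing"] == 25.0
        assert pooled.loc["mut", "percent_blebbing"] == 75.0
        assert pooled.loc["wt", "form_factor_mean"] == pytest.approx(0.875)
        assert len(summary) == 6  # 2 replicates + pooled, per condition
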