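"""Tissue detection, superpixel segmentation, and 1-NN compartment classes."""

import numpy as np
import pandas as pd
import pytest

import wmnquant as w
from wmnquant.compartments import (
    CLASS_IDS,
    FEATURE_COLUMNS,
    SegmentMap,
    train_compartment_classifier,
)
from wmnquant.pipeline import auto_training_labels
from wmnquant.roi import rasterize_polygon
from wmnquant.synthetic import SlideImage


def flat_slide(level=120, rows=1500, cols=1500):
    rgb = np.full((rows, cols, 3), level, dtype=np.uint8)
    return SlideImage(rgb=rgb, mpp=1.0, thickness_T=17.0)


class TestDetectTissue:
    def test_blank_image_gives_empty_mask(self):
        white = flat_slide(level=250, rows=400, cols=400)
        assert not w.detect_tissue(white).any()

    def test_tissue_mask_matches_truth_polygon(self, cortex_slide):
        config, slide, truth = cortex_slide
        mask = w.detect_tissue(slide)
        ref = rasterize_polygon(truth.geometry.tissue, slide.shape, config.mpp)
        jaccard = (mask & ref).sum() / (mask | ref).sum()
        assert jaccard >= 0.98

    def test_minimum_size_rule_at_450_um2(self):
        """A 400 μm² speck is removed, a 500 μm² speck retained."""
        rgb = np.full((600, 600, 3), 250, dtype=np.uint8)
        rgb[100:120, 100:120] = 80  # 20 x 20 = 400 μm²
        rgb[300:320, 300:325] = 80  # 20 x 25 = 500 μm²
        img = SlideImage(rgb=rgb, mpp=1.0, thickness_T=17.0)
        mask = w.detect_tissue(img)
        assert not mask[100:120, 100:120].any()
        assert mask[300:320, 300:325].sum() == 500

    def test_missing_mpp_rejected(self, wm_slide):
        _, slide, _ = wm_slide
        broken = SlideImage(rgb=slide.rgb, mpp=0.0, thickness_T=17.0)
        with pytest.raises(ValueError, match="mpp"):
            w.detect_tissue(broken)


class TestSuperpixels:
    def test_flat_tissue_gives_near_equal_segments(self):
        img = flat_slide()
        tissue = np.ones(img.shape, dtype=bool)
        segs = w.segment_superpixels(img, tissue, scale=0.4)
        areas = segs.features["area_um2"].to_numpy()
        assert areas.std() / areas.mean() < 0.5

    def test_segment_count_monotone_in_scale(self):
        img = flat_slide(rows=900, cols=900)
        tissue = np.ones(img.shape, dtype=bool)
        counts = [
            len(w.segment_superpixels(img, tissue, scale=s).features)
            for s in (1.2, 0.6, 0.3)
        ]
        assert counts[0] <= counts[1] <= counts[2]

    def test_every_tissue_pixel_has_exactly_one_segment(self, cortex_slide):
        _, slide, _ = cortex_slide
        tissue = w.detect_tissue(slide)
        segs = w.segment_superpixels(slide, tissue)
        assert (segs.labels[tissue] > 0).all()
        ids = segs.features.index
        assert ids.is_unique
        assert set(np.unique(segs.labels[tissue])) <= set(ids)

    def test_non_positive_scale_rejected(self):
        img = flat_slide(rows=300, cols=300)
        with pytest.raises(ValueError, match="scale"):
            w.segment_superpixels(img, np.ones(img.shape, dtype=bool), scale=0.0)


def toy_segment_map():
    """A hand-built segment map: 4 segments in a 40x40 raster."""
    labels = np.zeros((40, 40), dtype=int)
    labels[:20, :20] = 1
    labels[:20, 20:] = 2
    labels[20:, :20] = 3
    labels[20:, 20:] = 4
    feats = pd.DataFrame(
        {
            "mean_r": [200.0, 180.0, 90.0, 95.0],
            "mean_g": [200.0, 170.0, 60.0, 65.0],
            "mean_b": [210.0, 200.0, 50.0, 55.0],
            "mean_dab_od": [0.01, 0.05, 0.8, 0.75],
            "mean_haem_od": [0.0, 0.15, 0.15, 0.15],
            "nucleus_density": [0.0, 50.0, 900.0, 850.0],
            "tissue_fraction": [0.0, 1.0, 1.0, 1.0],
            "centroid_x_um": [10.0, 30.0, 10.0, 30.0],
            "centroid_y_um": [10.0, 10.0, 30.0, 30.0],
            "area_um2": [400.0] * 4,
        },
        index=pd.Index([1, 2, 3, 4], name="segment_id"),
    )
    return SegmentMap(labels=labels, features=feats, mpp=1.0)


class TestClassifier:
    def test_training_segments_self_consistent(self):
        segs = toy_segment_map()
        clf = train_compartment_classifier(
            segs, [(1, "background"), (2, "white_matter"), (3, "cortex")]
        )
        preds = clf.predict(segs.features.loc[[1, 2, 3], FEATURE_COLUMNS].to_numpy())
        assert preds == ["background", "white_matter", "cortex"]

    def test_conflicting_duplicate_labels_rejected(self):
        segs = toy_segment_map()
        with pytest.raises(ValueError, match="labelled both"):
            train_compartment_classifier(segs, [(1, "cortex"), (1, "white_matter")])

    def test_missing_required_class_rejected(self):
        segs = toy_segment_map()
        with pytest.raises(ValueError, match="cortex"):
            train_compartment_classifier(
                segs, [(1, "background")], required_classes=("background", "cortex")
            )

    def test_unknown_segment_id_rejected(self):
        segs = toy_segment_map()
        with pytest.raises(ValueError, match="not present"):
            train_compartment_classifier(segs, [(99, "cortex")])

    def test_wm_sliver_reassigned_to_border(self):
        """A white-matter component under 10% relative area becomes border."""
        segs = toy_segment_map()
        clf = train_compartment_classifier(
            segs, [(1, "background"), (3, "white_matter"), (2, "cortex")]
        )
        # segment 4 becomes a detached 4-px sliver in the far corner (its
        # features still look like white matter), segment 3 takes the rest
        segs.labels[20:, 20:] = 3
        segs.labels[0, 36:] = 4
        cmap = w.classify_compartments(segs, clf, border_filter_relative_area=0.1)
        assert (cmap.labels[0, 36:] == CLASS_IDS["border"]).all()
        assert (cmap.labels[20:, :] == CLASS_IDS["white_matter"]).all()


class TestEndToEndClassification:
    @pytest.fixture(scope="class")
    def classified(self, cortex_slide):
        config, slide, truth = cortex_slide
        tissue = w.detect_tissue(slide)
        segs = w.segment_superpixels(slide, tissue)
        examples = auto_training_labels(segs, truth)
        clf = w.train_compartment_classifier(segs, examples)
        cmap = w.classify_compartments(segs, clf, tissue_mask=tissue)
        return config, slide, truth, tissue, cmap

    def test_wm_truth_area_mostly_classified_wm(self, classified):
        config, slide, truth, _, cmap = classified
        wm_ref = rasterize_polygon(truth.geometry.white_matter, slide.shape, config.mpp)
        wm_pred = cmap.mask("white_matter")
        assert (wm_pred & wm_ref).sum() / wm_ref.sum() >= 0.95

    def test_automated_wm_at_least_as_large_as_margin_excluded_manual(self, classified):
        config, slide, truth, tissue, cmap = classified
        auto_area = cmap.mask("white_matter").sum()
        from wmnquant.pipeline import _truth_cortex_mask
        from wmnquant.stereology import wm_truth_roi

        roi = wm_truth_roi(truth, slide.shape)
        manual = w.exclude_boundary_margin(roi, _truth_cortex_mask(truth, slide.shape), 0.5)
        assert auto_area * config.mpp**2 / 1e6 >= manual.area_mm2

    def test_classification_is_deterministic(self, classified, cortex_slide):
        config, slide, truth = cortex_slide
        _, _, _, tissue, cmap = classified
        segs = w.segment_superpixels(slide, tissue)
        clf = w.train_compartment_classifier(segs, auto_training_labels(segs, truth))
        again = w.classify_compartments(segs, clf, tissue_mask=tissue)
        assert np.array_equal(again.labels, cmap.labels)

    def test_labels_exhaustive_and_exclusive(self, classified):
        *_, cmap = classified
        assert set(np.unique(cmap.labels)) <= {0, 1, 2, 3}
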