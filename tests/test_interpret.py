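"""Object segmentation, Gram/shape calls, arrangement analysis and the
slide-level aggregation."""

import numpy as np
import pytest

import holostain as hs
from holostain.interpret import ObjectDetection, SegmentationParams, _vote
from holostain.reconstruct import ColorImage


def _blank_image(n=128, pitch=0.25):
    rgb = np.ones((n, n, 3))
    return ColorImage(rgb=rgb, focus_map=np.zeros((n, n)), pitch=pitch)


def _detection(x, y, diameter=1.0, aspect=1.0, hue=280.0, shape=None,
               gram=None, n=128, pitch=0.25):
    mask = np.zeros((n, n), bool)
    r = max(int(diameter / (2 * pitch)), 1)
    ci, cj = int(y / pitch), int(x / pitch)
    mask[ci - r:ci + r + 1, cj - r:cj + r + 1] = True
    d = ObjectDetection(
        mask=mask, centroid=(x, y), area=np.pi * (diameter / 2) ** 2,
        circularity=0.9, aspect_ratio=aspect, hue_mean_deg=hue,
        hue_dispersion=0.05, focus_z=600.0)
    if shape or gram:
        d.shape_call, d.gram_call = shape, gram
        d.gram_confidence = 0.8
    return d


@pytest.fixture(scope="module")
def reconstructed_scene(cfg256):
    """Noiseless round trip of a sparse GNB phantom, interpreted."""
    ph = hs.generate_phantom(cfg256, "GNB", 1200, 0.0, seed=21, z_span=0.0,
                             red_cell_density=0.0)
    holo = hs.record_hologram(ph, cfg256, seed=21, noise=hs.NOISELESS)
    stack = hs.gs_reconstruct(holo, holo.z_true, max_iters=30)
    image = hs.compose_color(stack)
    return ph, image


class TestSegmentation:
    def test_blank_image_gives_no_detections(self):
        assert hs.segment_objects(_blank_image()) == []

    def test_object_count_matches_phantom(self, reconstructed_scene):
        ph, image = reconstructed_scene
        detections = hs.segment_objects(image)
        k = len(ph.bacteria)
        assert k > 0
        assert abs(len(detections) - k) <= max(1, round(0.2 * k))

    def test_masks_pairwise_disjoint(self, reconstructed_scene):
        _, image = reconstructed_scene
        detections = hs.segment_objects(image)
        total = np.zeros(image.rgb.shape[:2], int)
        for d in detections:
            total += d.mask
        assert total.max() <= 1

    def test_detection_invariants(self, reconstructed_scene):
        _, image = reconstructed_scene
        for d in hs.segment_objects(image):
            assert 0 < d.circularity <= 1
            assert d.aspect_ratio >= 1
            assert d.mask.any()
            assert 0 <= d.hue_mean_deg < 360


class TestGramAndShape:
    def test_reconstructed_gp_coccus_called_positive_coccus(self, cfg256):
        ph = hs.generate_phantom(cfg256, "GPC_pairs_chains", 800, 0.0,
                                 seed=31, z_span=0.0, red_cell_density=0.0)
        holo = hs.record_hologram(ph, cfg256, seed=31, noise=hs.NOISELESS)
        stack = hs.gs_reconstruct(holo, holo.z_true, max_iters=30)
        detections = hs.interpret_image(hs.compose_color(stack))
        assert detections
        grams = [d.gram_call for d in detections]
        assert grams.count("positive") / len(grams) >= 0.8

    def test_round_mask_is_coccus(self):
        d = hs.gram_and_shape(_detection(10, 10, aspect=1.0, hue=280))
        assert d.shape_call == "coccus" and d.gram_call == "positive"

    def test_four_by_one_rod_is_bacillus(self):
        d = hs.gram_and_shape(_detection(10, 10, aspect=4.0, hue=335))
        assert d.shape_call == "bacillus" and d.gram_call == "negative"

    def test_hue_tie_goes_to_nearer_band_centre(self):
        params = SegmentationParams()
        mid = (params.purple_hue_deg + params.pink_hue_deg) / 2
        d = hs.gram_and_shape(_detection(10, 10, hue=mid - 1.0), params)
        assert d.gram_call == "positive"
        d = hs.gram_and_shape(_detection(10, 10, hue=mid + 1.0), params)
        assert d.gram_call == "negative"


class TestArrangement:
    def test_collinear_run_is_pair_chain(self):
        dets = [_detection(10 + 1.05 * i, 10, 1.0) for i in range(6)]
        assert hs.arrangement(dets) == ["pair_chain"] * 6

    def test_isolated_coccus_is_singleton(self):
        dets = [_detection(10, 10), _detection(40, 40)]
        assert hs.arrangement(dets) == ["singleton", "singleton"]

    def test_compact_clump_is_cluster(self):
        rng = np.random.default_rng(0)
        dets = []
        placed = []
        while len(dets) < 10:
            x, y = 16 + rng.normal(0, 1.3, 2)
            if all((x - a) ** 2 + (y - b) ** 2 >= 1.0 for a, b in placed):
                placed.append((x, y))
                dets.append(_detection(x, y, 1.0))
        labels = hs.arrangement(dets)
        assert labels.count("cluster") >= 8

    def test_empty_input(self):
        assert hs.arrangement([]) == []


class TestSlideCall:
    def test_zero_detections_is_undefined(self):
        call = hs.slide_call([], (64, 64))
        assert call.category == "Undefined"
        assert call.n_objects == 0
        assert call.attention_map.max() == 0

    def test_majority_wins(self):
        dets = [_detection(5 + i, 5, shape="bacillus", gram="negative")
                for i in range(12)]
        for d in dets:
            d.arrangement = "singleton"
        call = hs.slide_call(dets, (128, 128))
        assert call.category == "GNB"
        assert call.evidence["GNB"] == 12

    def test_even_split_is_undefined(self):
        dets = []
        for i in range(6):
            d = _detection(5 + 3 * i, 5, shape="bacillus", gram="negative")
            d.arrangement = "singleton"
            dets.append(d)
        for i in range(6):
            d = _detection(5 + 3 * i, 20, shape="coccus", gram="positive")
            d.arrangement = "cluster"
            dets.append(d)
        call = hs.slide_call(dets, (128, 128), majority_frac=0.6)
        assert call.category == "Undefined"

    def test_min_objects_floor(self):
        dets = [_detection(5 + 3 * i, 5, shape="bacillus", gram="negative")
                for i in range(5)]
        for d in dets:
            d.arrangement = "singleton"
        assert hs.slide_call(dets, (128, 128), min_objects=10).category == \
            "Undefined"
        assert hs.slide_call(dets, (128, 128), min_objects=5).category == "GNB"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        dets = []
        for i in range(8):
            d = _detection(4 + 3 * i, 8, shape="bacillus", gram="negative")
            d.arrangement = "singleton"
            dets.append(d)
        for i in range(3):
            d = _detection(4 + 3 * i, 24, shape="coccus", gram="positive")
            d.arrangement = "cluster"
            dets.append(d)
        call_a = hs.slide_call(dets, (128, 128))
        order = rng.permutation(len(dets))
        call_b = hs.slide_call([dets[i] for i in order], (128, 128))
        assert call_a.category == call_b.category
        assert np.array_equal(call_a.attention_map, call_b.attention_map)

    def test_attention_supported_only_on_detection_masks(self):
        dets = [_detection(5 + 3 * i, 5, shape="bacillus", gram="negative")
                for i in range(11)]
        for d in dets:
            d.arrangement = "singleton"
        call = hs.slide_call(dets, (128, 128))
        union = np.zeros((128, 128), bool)
        for d in dets:
            union |= d.mask
        assert not call.attention_map[~union].any()
        assert call.attention_map.max() == pytest.approx(1.0)

    def test_vote_mapping(self):
        d = _detection(5, 5, shape="coccus", gram="positive")
        d.arrangement = "cluster"
        assert _vote(d) == "GPC_clusters"
        d.arrangement = "pair_chain"
        assert _vote(d) == "GPC_pairs_chains"
        d.arrangement = "singleton"
        assert _vote(d) is None
        d.shape_call, d.gram_call = "bacillus", "negative"
        assert _vote(d) == "GNB"
        d.degenerate = True
        assert _vote(d) is None

    def test_attention_overlay_shape(self):
        img = _blank_image()
        dets = [_detection(5, 5, shape="bacillus", gram="negative")
                for _ in range(1)]
        dets[0].arrangement = "singleton"
        call = hs.slide_call(dets, (128, 128), min_objects=1)
        overlay = hs.attention_overlay(img, call)
        assert overlay.shape == img.rgb.shape
        assert overlay.min() >= 0 and overlay.max() <= 1
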