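import numpy as np
import pytest

from uricads.model import (
    ModelConfig,
    SCDCNN,
    box_iou_matrix,
    decode_detections,
    mask_to_rle,
    nms,
    rle_to_mask,
    select_kidney_component,
)


@pytest.fixture(scope="module")
def features_96(tiny_model, lesion_phantom):
    img, _ = lesion_phantom
    T = tiny_model.backbone_forward(img)
    return T, tiny_model.fpn_forward(T, "image"), \
        tiny_model.fpn_forward(T, "region")


class TestBackbone:
    def test_stride_and_channel_schedule_tiny(self, tiny_model):
        T = tiny_model.backbone_forward(np.zeros((96, 96)))
        for l in range(1, 5):
            assert T[l].shape == (4 * 2 ** l, 96 // 2 ** l, 96 // 2 ** l)

    def test_default_width_matches_resnet50_channels(self):
        cfg = ModelConfig()  # width base 128
        model = SCDCNN(cfg)
        T = model.backbone_forward(np.zeros((64, 64)))
        assert [T[l].shape[0] for l in range(1, 5)] == [256, 512, 1024, 2048]
        assert T[4].shape[-2:] == (4, 4)

    def test_256_input_gives_16x16_top_map(self, tiny_model):
        T = tiny_model.backbone_forward(np.zeros((256, 256)))
        assert T[4].shape[-2:] == (16, 16)

    def test_schedule_holds_for_any_divisible_size(self, tiny_model):
        for H, W in [(32, 48), (48, 96), (160, 112)]:
            T = tiny_model.backbone_forward(np.zeros((H, W)))
            for l in range(1, 5):
                assert T[l].shape[-2:] == (H // 2 ** l, W // 2 ** l)

    def test_undersized_or_indivisible_image_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.backbone_forward(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            tiny_model.backbone_forward(np.zeros((100, 96)))

    def test_deterministic_forward(self, tiny_model, lesion_phantom):
        img, _ = lesion_phantom
        a = tiny_model.forward_case(img)
        b = tiny_model.forward_case(img)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.p_image, b.p_image)
        np.testing.assert_array_equal(a.regions, b.regions)


class TestFPN:
    def test_fixed_channel_count_across_scales(self, tiny_model, features_96):
        T, F_img, F_reg = features_96
        C = tiny_model.config.fpn_channels
        for l in range(1, 5):
            assert F_img[l].shape[0] == C and F_reg[l].shape[0] == C
            assert F_img[l].shape[-2:] == T[l].shape[-2:]

    def test_roles_use_independent_parameters(self, tiny_model, features_96):
        _, F_img, F_reg = features_96
        assert not np.allclose(F_img[1].data, F_reg[1].data)

    def test_unknown_role_rejected(self, tiny_model, features_96):
        T, _, _ = features_96
        with pytest.raises(ValueError):
            tiny_model.fpn_forward(T, "segmentation")


class TestClassifier:
    def test_output_length_seven_in_unit_interval(self, tiny_model, features_96):
        T, _, _ = features_96
        p = tiny_model.classify_image(T[4])
        assert p.shape == (7,)
        assert np.all(p >= 0) and np.all(p <= 1)

    def test_zero_logits_give_half(self, tiny_model):
        saved_w = tiny_model.cls_head.weight.data.copy()
        saved_b = tiny_model.cls_head.bias.data.copy()
        tiny_model.cls_head.weight.data[:] = 0.0
        tiny_model.cls_head.bias.data[:] = 0.0
        try:
            T = tiny_model.backbone_forward(np.zeros((96, 96)))
            np.testing.assert_allclose(tiny_model.classify_image(T[4]), 0.5)
        finally:
            tiny_model.cls_head.weight.data = saved_w
            tiny_model.cls_head.bias.data = saved_b

    def test_heads_are_per_category_independent(self, tiny_model, features_96):
        T, _, _ = features_96
        base = tiny_model.classify_image(T[4])
        tiny_model.cls_head.bias.data[2] += 1.0
        try:
            bumped = tiny_model.classify_image(T[4])
        finally:
            tiny_model.cls_head.bias.data[2] -= 1.0
        assert bumped[2] != base[2]
        np.testing.assert_array_equal(np.delete(bumped, 2), np.delete(base, 2))


class TestSegmentation:
    def test_mask_is_binary_at_full_resolution(self, tiny_model, features_96):
        _, F_img, _ = features_96
        mask, found = tiny_model.segment_kidney(F_img)
        assert mask.shape == (96, 96)
        assert set(np.unique(mask)) <= {0, 1}

    def test_no_candidate_yields_empty_mask_and_flag(self):
        mask, found = select_kidney_component(np.full((8, 8), 0.2), 0.5)
        assert not found and mask.sum() == 0

    def test_boundary_probability_included(self):
        prob = np.zeros((8, 8))
        prob[3, 3] = 0.5
        mask, found = select_kidney_component(prob, 0.5)
        assert found and mask[3, 3] == 1

    def test_highest_scoring_component_kept(self):
        prob = np.zeros((10, 10))
        prob[1:3, 1:3] = 0.7
        prob[6:9, 6:9] = 0.9
        mask, found = select_kidney_component(prob, 0.5)
        assert found
        assert mask[7, 7] == 1 and mask[2, 2] == 0


class TestDetection:
    def _candidate_setup(self, seed, n_classes=4):
        rng = np.random.default_rng(seed)
        A, h, w = 2, 6, 6
        probs = rng.uniform(0, 1, (A, n_classes, h, w)) ** 3
        deltas = rng.normal(scale=0.1, size=(A, 4, h, w))
        size = 8
        cx = (np.arange(w) + 0.5) * 4
        cy = (np.arange(h) + 0.5) * 4
        anchors = []
        for s in (8, 16):
            gx, gy = np.meshgrid(cx, cy)
            anchors.append(np.stack([gx - s / 2, gx + s / 2,
                                     gy - s / 2, gy + s / 2], -1).reshape(-1, 4))
        return probs, deltas, np.concatenate(anchors)

    def test_survivors_exceed_threshold_with_single_class(self):
        probs, deltas, anchors = self._candidate_setup(1)
        regions, _ = decode_detections(probs, deltas, anchors, (24, 24),
                                       0.5, 0.5)
        if len(regions):
            assert np.all(regions[:, 5] > 0.5)
            assert np.all((regions[:, 4] >= 1) & (regions[:, 4] <= 4))
            assert np.all(regions[:, 0] < regions[:, 1])
            assert np.all(regions[:, 2] < regions[:, 3])

    def test_threshold_filter_semantics(self):
        # two disjoint candidates at scores 0.4 / 0.6 -> one survivor at 0.5
        probs = np.zeros((1, 1, 1, 2))
        probs[0, 0, 0, 0] = 0.4
        probs[0, 0, 0, 1] = 0.6
        logit = np.log(probs / (1 - probs + 1e-12) + 1e-12)
        deltas = np.zeros((1, 4, 1, 2))
        anchors = np.array([[0.0, 8.0, 0.0, 8.0], [40.0, 48.0, 0.0, 8.0]])
        from uricads.model import _stable_sigmoid
        regions, _ = decode_detections(_stable_sigmoid(logit), deltas, anchors,
                                       (48, 48), 0.5, 0.5)
        assert regions.shape[0] == 1
        assert regions[0, 5] == pytest.approx(0.6, abs=1e-9)

    def test_monotone_in_threshold(self, tiny_model, features_96):
        _, _, F_reg = features_96
        prev = None
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            regions = tiny_model.detect_regions(F_reg, thr, (96, 96))
            rows = {tuple(r) for r in regions.tolist()}
            if prev is not None:
                assert rows <= prev
            prev = rows

    def test_matches_bruteforce_filter_on_random_candidates(self):
        """Survivor sets equal a naive per-candidate loop (NMS then filter)."""
        for seed in range(10):
            probs, deltas, anchors = self._candidate_setup(seed)
            regions, _ = decode_detections(probs, deltas, anchors, (24, 24),
                                           0.35, 0.5)
            # naive oracle: argmax class, greedy NMS per class, then filter
            A, L, h, w = probs.shape
            flat_p = probs.transpose(0, 2, 3, 1).reshape(-1, L)
            ids = flat_p.argmax(1)
            scores = flat_p.max(1)
            flat_d = deltas.transpose(0, 2, 3, 1).reshape(-1, 4)
            naive = []
            for k in range(L):
                idxs = [i for i in range(len(ids)) if ids[i] == k]
                boxes = {}
                for i in idxs:
                    acx = (anchors[i, 0] + anchors[i, 1]) / 2
                    acy = (anchors[i, 2] + anchors[i, 3]) / 2
                    aw = anchors[i, 1] - anchors[i, 0]
                    ah = anchors[i, 3] - anchors[i, 2]
                    cx = acx + flat_d[i, 0] * aw
                    cy = acy + flat_d[i, 1] * ah
                    bw = aw * np.exp(flat_d[i, 2])
                    bh = ah * np.exp(flat_d[i, 3])
                    box = np.array([max(cx - bw / 2, 0), min(cx + bw / 2, 24),
                                    max(cy - bh / 2, 0), min(cy + bh / 2, 24)])
                    if box[0] < box[1] and box[2] < box[3]:
                        boxes[i] = box
                alive = sorted(boxes, key=lambda i: -scores[i])
                kept = []
                while alive:
                    best = alive.pop(0)
                    kept.append(best)
                    alive = [i for i in alive
                             if box_iou_matrix(boxes[best], boxes[i])[0, 0]
                             <= 0.5]
                for i in kept:
                    if scores[i] > 0.35:
                        naive.append((k + 1, round(scores[i], 12),
                                      tuple(np.round(boxes[i], 9))))
            got = {(int(r[4]), round(r[5], 12),
                    tuple(np.round([r[0], r[1], r[2], r[3]], 9)))
                   for r in regions.tolist()}
            assert got == set(naive)


class TestNMS:
    def test_suppresses_overlap_keeps_disjoint(self):
        boxes = np.array([[0, 10, 0, 10], [1, 11, 1, 11], [30, 40, 30, 40]])
        keep = nms(boxes, np.array([0.9, 0.8, 0.7]), 0.5)
        assert list(keep) == [0, 2]

    def test_iou_matrix_known_values(self):
        a = np.array([[0, 2, 0, 2]])
        b = np.array([[1, 3, 0, 2], [4, 6, 4, 6]])
        np.testing.assert_allclose(box_iou_matrix(a, b)[0], [1 / 3, 0.0])


class TestTripletAndPersistence:
    def test_forward_case_triplet_contract(self, tiny_model, lesion_phantom):
        img, _ = lesion_phantom
        t = tiny_model.forward_case(img)
        assert t.mask.shape == img.shape
        assert t.p_image.shape == (7,)
        assert t.regions.ndim == 2 and t.regions.shape[1] == 6

    def test_save_load_reproduces_outputs(self, tiny_model, lesion_phantom,
                                          tmp_path):
        img, _ = lesion_phantom
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        clone = SCDCNN.load(path)
        a, b = tiny_model.forward_case(img), clone.forward_case(img)
        np.testing.assert_array_equal(a.p_image, b.p_image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_rle_round_trip(self):
        rng = np.random.default_rng(9)
        mask = (rng.random((17, 23)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(rle_to_mask(mask_to_rle(mask)), mask)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = ModelConfig.tiny(seed=5)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = ModelConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg
        assert back.digest() == cfg.digest()
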