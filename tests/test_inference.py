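import numpy as np
import pytest

from drseg import inference as inf
from drseg import phantoms, volio
from drseg.inference import (
    PostprocPolicy,
    ProbabilityMaps,
    ensemble_segment,
    largest_component_filter,
    segment_volume,
    sliding_window_predict,
)
from drseg.volio import IntensityVolume, LabeledVolume

from conftest import perfect_stub_model

RIM = 999


def _truth_and_image(seed=11, shape=(48, 48, 48), spacing=(0.7,) * 3):
    spec = phantoms.PhantomSpec(shape=shape, spacing=spacing, seed=seed)
    lm = phantoms.make_phantom_labelmap(spec)
    truth = lm.copy()
    truth.data[truth.data == RIM] = 0
    del truth.lut[RIM]
    rng = np.random.default_rng(seed)
    spec.contrast_profile = phantoms.default_contrast_profile(lm, 30.0, rng)
    img = phantoms.render_validation_image(lm, spec)
    return truth, img


@pytest.fixture(scope="module")
def truth_image():
    return _truth_and_image()


@pytest.fixture(scope="module")
def stub(truth_image):
    truth, _ = truth_image
    class_labels = (0,) + tuple(truth.present_labels())
    lia_truth = volio.reorient(truth, "LIA")
    return perfect_stub_model(lia_truth, class_labels), class_labels


class TestSlidingWindow:
    def test_full_volume_patch_equals_single_pass(self, truth_image, stub):
        truth, img = truth_image
        model, class_labels = stub[0], stub[1]
        lia_img = volio.reorient(img, "LIA")
        pm = sliding_window_predict(model, lia_img, patch=lia_img.shape, overlap=0.5)
        single = model.net.forward(np.zeros((1, 1) + lia_img.shape, np.float32))
        from drseg.network.unet import softmax

        assert np.allclose(pm.probs, softmax(single[0].astype(np.float64), axis=0))

    def test_probabilities_sum_to_one_with_overlap(self, truth_image, stub):
        truth, img = truth_image
        model = stub[0]
        lia_img = volio.reorient(img, "LIA")
        pm = sliding_window_predict(model, lia_img, patch=(48, 48, 48), overlap=0.5)
        assert np.allclose(pm.probs.sum(axis=0), 1.0, atol=1e-6)

    def test_weighted_average_oracle_1d_tiling(self):
        # hand-check the weighted accumulation on a 2-tile overlap
        starts = inf._tile_starts(6, 4, 0.5)
        assert starts == [0, 2]
        w1d = np.exp(-0.5 * ((np.arange(4) - 1.5) / 0.5) ** 2)  # sigma = 4/8
        acc = np.zeros(6)
        ws = np.zeros(6)
        vals = {0: 1.0, 2: 3.0}
        for s in starts:
            acc[s:s + 4] += vals[s] * w1d
            ws[s:s + 4] += w1d
        out = acc / ws
        # voxels covered by one tile keep that tile's value; overlapping
        # voxels lie strictly between
        assert out[0] == pytest.approx(1.0)
        assert out[5] == pytest.approx(3.0)
        assert 1.0 < out[2] < 3.0


class TestEnsemble:
    def _pm(self, probs):
        return ProbabilityMaps(np.asarray(probs), np.eye(4), (0, 1))

    def test_single_model_is_argmax(self):
        p = np.zeros((2, 2, 2, 2))
        p[0] = 0.7
        p[1] = 0.3
        seg = ensemble_segment([self._pm(p)])
        assert np.all(seg.data == 0)

    def test_five_identical_same_as_one(self):
        rng = np.random.default_rng(0)
        a = rng.random((1, 3, 3, 3))
        p = np.concatenate([a, 1 - a])
        one = ensemble_segment([self._pm(p)])
        five = ensemble_segment([self._pm(p)] * 5)
        assert np.array_equal(one.data, five.data)

    def test_mean_arithmetic(self):
        p1 = np.zeros((2, 1, 1, 1))
        p1[0], p1[1] = 0.6, 0.4
        p2 = np.zeros((2, 1, 1, 1))
        p2[0], p2[1] = 0.2, 0.8
        seg = ensemble_segment([self._pm(p1), self._pm(p2)])
        assert seg.data[0, 0, 0] == 1  # mean (0.4, 0.6) -> class index 1

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(3):
            a = rng.random((1, 4, 4, 4))
            ps.append(self._pm(np.concatenate([a, 1 - a])))
        seg_a = ensemble_segment(ps)
        seg_b = ensemble_segment(ps[::-1])
        assert np.array_equal(seg_a.data, seg_b.data)

    def test_grid_mismatch_rejected(self):
        p = np.full((2, 2, 2, 2), 0.5)
        q = np.full((2, 3, 3, 3), 0.5)
        with pytest.raises(ValueError):
            ensemble_segment([self._pm(p), self._pm(q)])


class TestLargestComponent:
    def _seg(self, data, labels=(7,)):
        lut = {int(l): (f"l{l}", (0, 0, 0)) for l in labels}
        return LabeledVolume(np.asarray(data, np.int32), np.eye(4), lut)

    def test_small_component_removed(self):
        data = np.zeros((10, 10, 10), np.int32)
        data[1:3, 1:3, 1:3] = 7  # 8 voxels
        data[7, 7, 7] = 7  # satellite
        seg = self._seg(data)
        out = largest_component_filter(seg, PostprocPolicy({7}))
        assert out.data[7, 7, 7] == 0
        assert (out.data == 7).sum() == 8

    def test_single_component_unchanged(self):
        data = np.zeros((6, 6, 6), np.int32)
        data[2:4, 2:4, 2:4] = 7
        seg = self._seg(data)
        out = largest_component_filter(seg, PostprocPolicy({7}))
        assert np.array_equal(out.data, seg.data)

    def test_excluded_label_keeps_all_components(self):
        data = np.zeros((10, 10, 10), np.int32)
        data[0, 0, 0] = 5
        data[9, 9, 9] = 5
        seg = self._seg(data, labels=(5,))
        out = largest_component_filter(seg, PostprocPolicy({7}))
        assert (out.data == 5).sum() == 2

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        data = (rng.random((12, 12, 12)) > 0.7).astype(np.int32) * 3
        seg = self._seg(data, labels=(3,))
        pol = PostprocPolicy({3}, connectivity=6)
        once = largest_component_filter(seg, pol)
        twice = largest_component_filter(once, pol)
        assert np.array_equal(once.data, twice.data)

    def test_connectivity_matters(self):
        data = np.zeros((6, 6, 6), np.int32)
        data[1, 1, 1] = 3
        data[2, 2, 2] = 3  # diagonal: connected at 26, not at 6
        data[4:6, 4:6, 4:6] = 3
        seg = self._seg(data, labels=(3,))
        out26 = largest_component_filter(seg, PostprocPolicy({3}, connectivity=26))
        out6 = largest_component_filter(seg, PostprocPolicy({3}, connectivity=6))
        assert (out26.data == 3).sum() == 8
        assert (out6.data == 3).sum() == 8
        # diagonal pair survives as one component at 26 but splits at 6
        comps26 = (out26.data[1, 1, 1], out6.data[1, 1, 1])
        assert comps26 == (0, 0)


class TestDecidePolicy:
    def test_satellite_errors_include_label(self, truth_image):
        truth, img = truth_image
        # stub that predicts truth plus a spurious satellite for label 2
        noisy = truth.copy()
        noisy.data[1, 1, 1] = 2
        class_labels = (0,) + tuple(truth.present_labels())
        model = perfect_stub_model(noisy, class_labels)
        pol = inf.decide_postproc_policy([model], [(img, truth)])
        assert 2 in pol.apply_largest_component

    def test_true_multicomponent_label_excluded(self, truth_image):
        truth, img = truth_image
        # ground truth genuinely has two components for label 17
        gt2 = truth.copy()
        gt2.data[1, 1, 1] = 17
        class_labels = (0,) + tuple(truth.present_labels())
        model = perfect_stub_model(gt2, class_labels)  # predicts both components
        pol = inf.decide_postproc_policy([model], [(img, gt2)])
        assert 17 not in pol.apply_largest_component

    def test_tie_excluded(self, truth_image):
        truth, img = truth_image
        class_labels = (0,) + tuple(truth.present_labels())
        model = perfect_stub_model(truth, class_labels)  # perfect: no change
        pol = inf.decide_postproc_policy([model], [(img, truth)])
        assert pol.apply_largest_component == frozenset()

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError):
            inf.decide_postproc_policy([], [])


class TestSegmentVolume:
    def test_perfect_stub_matched_spacing_dice_one(self, truth_image, stub):
        truth, img = truth_image
        model = stub[0]
        seg = segment_volume(img, [model], PostprocPolicy(), train_spacing=(0.7,) * 3,
                             lut=truth.lut)
        assert seg.shape == img.shape
        assert np.allclose(seg.affine, img.affine)
        for lab in truth.present_labels():
            g = truth.data == lab
            p = seg.data == lab
            assert 2 * (g & p).sum() / (g.sum() + p.sum()) == 1.0

    def test_output_label_set_subset_of_classes(self, truth_image, stub):
        truth, img = truth_image
        seg = segment_volume(img, [stub[0]], PostprocPolicy(),
                             train_spacing=(0.7,) * 3, lut=truth.lut)
        assert set(np.unique(seg.data)) <= set(stub[1])

    def test_affine_preserved_with_resampling(self):
        truth, img = _truth_and_image(seed=21, shape=(40, 40, 40), spacing=(0.8,) * 3)
        class_labels = (0,) + tuple(truth.present_labels())
        lia_truth = volio.reorient(truth, "LIA")
        lia07 = volio.resample_labels(lia_truth, (0.7, 0.7, 0.7))
        model = perfect_stub_model(lia07, class_labels)
        seg = segment_volume(img, [model], PostprocPolicy(), train_spacing=(0.7,) * 3,
                             lut=truth.lut)
        assert seg.shape == img.shape
        assert np.allclose(seg.affine, img.affine)
        assert np.allclose(seg.spacing, 0.8)
        # round trip through 0.7 mm and back keeps high agreement
        for lab in truth.present_labels():
            g = truth.data == lab
            p = seg.data == lab
            d = 2 * (g & p).sum() / (g.sum() + p.sum())
            assert d > 0.9

    def test_empty_model_list_rejected(self, truth_image):
        _, img = truth_image
        with pytest.raises(ValueError):
            segment_volume(img, [], PostprocPolicy())


class TestPolicySerialization:
    def test_json_roundtrip(self):
        pol = PostprocPolicy({2, 3, 41}, connectivity=18)
        back = PostprocPolicy.from_json(pol.to_json())
        assert back.apply_largest_component == pol.apply_largest_component
        assert back.connectivity == pol.connectivity

    def test_bad_connectivity(self):
        with pytest.raises(ValueError):
            PostprocPolicy(connectivity=7)
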