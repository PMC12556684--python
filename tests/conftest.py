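import numpy as np
import pytest

from drseg import phantoms, volio


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def phantom():
    """Default 64^3 / 0.7 mm phantom with 8 subcortical blobs."""
    return phantoms.make_phantom_labelmap(phantoms.PhantomSpec(seed=7))


@pytest.fixture
def small_phantom():
    """Cheap 32^3 phantom for fast structural tests."""
    spec = phantoms.PhantomSpec(shape=(32, 32, 32), n_subcortical=2, seed=3)
    return phantoms.make_phantom_labelmap(spec)


@pytest.fixture
def fs35_pair():
    """Random 35-label maps (gt == pred) carrying the full standard lut."""
    rng = np.random.default_rng(99)
    ids = np.array(sorted(volio.FS35_LUT))
    data = ids[rng.integers(0, len(ids), size=(12, 12, 12))].astype(np.int32)
    gt = volio.LabeledVolume(data, np.eye(4), dict(volio.FS35_LUT))
    return gt, gt.copy()


def perfect_stub_model(truth, class_labels):
    """Test double: a 'model' that predicts the true one-hot labels.

    Reorients its stored truth to match whatever grid orientation the
    incoming image has (the inference path hands it LIA data).
    """

    class _Cfg:
        n_stages = 1
        n_classes = len(class_labels)
        patch_size = truth.shape

    class _Net:
        cfg = _Cfg()

        def forward(self, x):
            data = truth.data
            if x.shape[2:] != data.shape:
                raise AssertionError(f"stub grid mismatch {x.shape[2:]} vs {data.shape}")
            logits = np.full((1, len(class_labels)) + data.shape, -20.0, dtype=np.float32)
            for idx, lab in enumerate(class_labels):
                logits[0, idx][data == lab] = 20.0
            return logits

    class _Stub:
        net = _Net()

        def __init__(self):
            self.class_labels = tuple(class_labels)
            self.fold_index = 0
            self.history = []

    return _Stub()
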