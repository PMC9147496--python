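import numpy as np
import pytest

from petcam import PhantomSpec, generate_cohort
from petcam.net import ClassifierConfig, MipClassifier


@pytest.fixture(scope="session")
def tiny_cohort():
    """Eight small phantom patients (24x24x48 voxels -> 48x24 MIPs)."""
    spec = PhantomSpec(
        volume_shape=(24, 24, 48), n_patients=8, seed=7, noise_sigma=0.2,
        outcome_flip_prob=0.0,
    )
    return generate_cohort(spec)


@pytest.fixture()
def tiny_classifier():
    """A frozen two-layer classifier small enough for finite differences."""
    config = ClassifierConfig(
        input_shape=(16, 8), channels=(2, 2), strides=(2, 2),
        dense_widths=(8, 4), dropout=0.0, seed=3,
    )
    return MipClassifier(config)


def finite_difference_influence(model, mip, class_index=1, eps=1e-5):
    """Central finite differences of y_hat^C w.r.t. the feature maps."""
    from petcam._nn import sigmoid

    pred = model.forward(mip[None], train=False)
    f0 = pred.feature_maps.copy()

    def prob(f):
        logit = model.head.forward(f, train=False)[0, 0]
        p = sigmoid(np.array([logit]))[0]
        return p if class_index == 1 else 1.0 - p

    grad = np.zeros_like(f0)
    it = np.nditer(f0, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        fp = f0.copy()
        fp[idx] += eps
        fm = f0.copy()
        fm[idx] -= eps
        grad[idx] = (prob(fp) - prob(fm)) / (2 * eps)
    return grad
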