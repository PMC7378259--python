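import numpy as np
import pytest

import histoblocks as hb


@pytest.fixture(scope="session")
def kb():
    return hb.default_kb()


@pytest.fixture(scope="session")
def class_descriptors():
    """A dozen labelled descriptors per classifier class, from the texture
    generator — separable by construction."""
    X, y = [], []
    for lab in hb.CLASSIFIER_LABELS:
        for s in range(12):
            X.append(hb.describe_block(hb.generate_block(lab, 4000 + s)))
            y.append(lab)
    return np.array(X), np.array(y)


@pytest.fixture(scope="session")
def trained_model(class_descriptors):
    X, y = class_descriptors
    return hb.train_cascade(X, y, hb.CascadeConfig(seed=0))


@pytest.fixture(scope="session")
def probe_descriptors():
    """Held-out descriptors (seeds disjoint from the training fixture)."""
    X, y = [], []
    for lab in hb.CLASSIFIER_LABELS:
        for s in range(6):
            X.append(hb.describe_block(hb.generate_block(lab, 9000 + s)))
            y.append(lab)
    return np.array(X), np.array(y)
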