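import warnings

import numpy as np
import pytest

from sklearn.exceptions import ConvergenceWarning

import burstclass as bc

warnings.filterwarnings("ignore", category=ConvergenceWarning)


@pytest.fixture(scope="session")
def small_captive():
    """20 bursts per class: enough to train a clean separable model fast."""
    return bc.generate_captive_dataset(
        {c: 20 for c in bc.CAPTIVE_COUNTS}, seed=42)


@pytest.fixture(scope="session")
def small_ann(small_captive):
    """A burst-level ANN classifier trained on the small captive set."""
    clf = bc.BurstClassifier(kind="ann", window_size=79, max_iter=60,
                             random_state=0)
    return clf.fit(small_captive)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
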