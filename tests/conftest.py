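import numpy as np
import pytest

from morphomap import LandmarkPair, Point2
from morphomap.workflows import run_recovery


def make_pairs(X, x, embryo_id="e1", interval_id="st22-23"):
    """Wrap coordinate arrays into LandmarkPair lists."""
    return [
        LandmarkPair(embryo_id, interval_id, Point2(*Xi), Point2(*xi))
        for Xi, xi in zip(np.asarray(X, float), np.asarray(x, float))
    ]


def affine_pairs(A, b, n=20, lo=0.0, hi=1000.0, seed=0, embryo_id="e1"):
    """Noiseless landmark pairs generated by the affine map x = A X + b."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(lo, hi, size=(n, 2))
    x = X @ np.asarray(A, float).T + np.asarray(b, float)
    return make_pairs(X, x, embryo_id=embryo_id)


@pytest.fixture(scope="session")
def recovery():
    """The default parameter-recovery experiment (8 embryos x 30 markers,
    sigma = 20 µm, fixed seed), shared across the suite."""
    return run_recovery(seed=1)
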