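import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def exhaustive_l0_support(design, observations, k):
    """Independent oracle: best k-subset by exhaustive least squares."""
    from itertools import combinations

    best = (np.inf, ())
    for subset in combinations(range(design.shape[1]), k):
        sub = design[:, list(subset)]
        w, *_ = np.linalg.lstsq(sub, observations, rcond=None)
        resid = observations - sub @ w
        score = float(resid @ resid)
        if score < best[0]:
            best = (score, subset)
    return set(best[1])
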