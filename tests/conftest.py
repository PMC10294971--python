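import numpy as np
import pytest

import ppgcvd as p


@pytest.fixture(scope="session")
def blobs100():
    """Well-separated Gaussian blobs at the pipeline's feature dimension."""
    X, y = p.generate_feature_blobs(500, 100, 10.0, seed=5)
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(y))
    return X[idx[:700]], y[idx[:700]], X[idx[700:]], y[idx[700:]]


@pytest.fixture(scope="session")
def small_cohort_segments():
    """A separable 8-subject cohort, segmented (480 one-second segments)."""
    spec = p.CohortSpec(
        n_cvd=4, n_normal=4, duration=60.0, morphology_shift=0.9, seed=3
    )
    return [p.segment(r) for r in p.generate_cohort(spec)]


@pytest.fixture(scope="session")
def planted_mask_data():
    """200-column rows: 100 informative columns (class-mean shift) at known
    positions, 100 pure-noise columns."""
    rng = np.random.default_rng(123)
    n_per = 250
    X = rng.normal(size=(2 * n_per, 200))
    informative = np.sort(rng.choice(200, size=100, replace=False))
    # a moderate per-column shift so the wrapper accuracy does not saturate
    X[:n_per, informative] += 0.4
    y = np.array([p.CVD] * n_per + [p.NORMAL] * n_per)
    return X, y, informative
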