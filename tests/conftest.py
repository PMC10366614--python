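import numpy as np
import pytest

import tvmanifold as tm


@pytest.fixture(scope="session")
def default_scan():
    """One synthetic multi-task scan at the default study conditions."""
    cfg = tm.SyntheticConfig(n_subjects=1, n_rois=30, seed=3)
    ts, schedule, truth = tm.generate_dataset(cfg)[0]
    return cfg, ts, schedule, truth


@pytest.fixture(scope="session")
def default_tvfc(default_scan):
    """Full-resolution (w_step=1) tvFC matrix for the default scan."""
    _, ts, schedule, _ = default_scan
    return tm.compute_tvfc(ts, tm.WindowSpec(30, 1), schedule)


@pytest.fixture(scope="session")
def mid_tvfc(default_scan):
    """Window-subsampled (w_step=3) tvFC matrix, large enough for the
    neighborhood sizes the hyper-parameter contrasts use."""
    _, ts, schedule, _ = default_scan
    return tm.compute_tvfc(ts, tm.WindowSpec(30, 3), schedule)


@pytest.fixture(scope="session")
def small_tvfc(default_scan):
    """Window-subsampled (w_step=5) tvFC matrix for optimization-heavy tests."""
    _, ts, schedule, _ = default_scan
    return tm.compute_tvfc(ts, tm.WindowSpec(30, 5), schedule)


@pytest.fixture(scope="session")
def gaussian_cloud():
    rng = np.random.default_rng(11)
    return rng.standard_normal((100, 5))


@pytest.fixture(scope="session")
def two_clusters():
    """Two well-separated Gaussian clusters with labels."""
    rng = np.random.default_rng(4)
    a = rng.standard_normal((30, 4))
    b = rng.standard_normal((30, 4)) + 12.0
    x = np.vstack([a, b])
    labels = ["a"] * 30 + ["b"] * 30
    return x, labels
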