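import numpy as np
import pytest

from overprint import PhantomConfig, PrintGeometry, SparseCube


def make_cube(height, width, n_peaks, events, meta=None):
    """Build a SparseCube from a list of (row, col, peak, count) tuples."""
    if events:
        r, c, k, n = (np.array(v, dtype=np.int64) for v in zip(*events))
    else:
        r = c = k = n = np.array([], dtype=np.int64)
    return SparseCube(height, width, n_peaks, r, c, k, n, meta=dict(meta or {}))


@pytest.fixture
def cube_2x2():
    return make_cube(2, 2, 3, [(0, 0, 0, 1), (0, 0, 1, 1), (1, 1, 2, 1)])


def small_config(seed=0, side=168, **overrides):
    """Default phantom geometry scaled to a small raster for fast tests."""
    s = side / 504.0
    defaults = dict(
        height=side, width=side,
        print_a=PrintGeometry(center=(252 * s, 182 * s), axes=(160 * s, 120 * s),
                              ridge_frequency=1 / 16, ridge_phase=0.3, ridge_angle=0.26),
        print_b=PrintGeometry(center=(252 * s, 322 * s), axes=(160 * s, 120 * s),
                              ridge_frequency=1 / 16, ridge_phase=1.1, ridge_angle=1.83),
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def pipeline_cache():
    """Memoized full bin-train-backfit-cluster runs on the default phantom,
    shared across acceptance tests (each run takes minutes)."""
    from overprint import default_config, run_pipeline

    cache = {}

    def get(seed: int, factor: int):
        key = (seed, factor)
        if key not in cache:
            cache[key] = run_pipeline(default_config(seed=seed),
                                      bin_factor=factor, seed=seed)
        return cache[key]

    return get
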