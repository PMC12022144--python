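import numpy as np
import pytest

from admixscan.core import PhasedPanel, build_site_table


def random_panel(rng, n_hap=None, n_sites=None, cm_scale=1.0):
    """Small random phased panel for property tests."""
    n_hap = n_hap or int(rng.integers(2, 17) // 2 * 2) or 2
    n_sites = n_sites or int(rng.integers(2, 41))
    H = (rng.random((n_hap, n_sites)) < rng.uniform(0.1, 0.9)).astype(np.uint8)
    pos = np.sort(rng.choice(np.arange(1, 10 * n_sites + 1), size=n_sites, replace=False))
    cm = pos * cm_scale / 100.0
    return PhasedPanel(H, pos.astype(np.int64), cm)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """Deterministic 6-haplotype, 8-site panel with one singleton."""
    H = np.array(
        [
            [0, 1, 0, 0, 1, 0, 1, 0],
            [0, 1, 0, 0, 0, 0, 1, 0],
            [1, 0, 0, 1, 0, 0, 0, 0],
            [0, 0, 0, 1, 0, 0, 0, 1],
            [0, 1, 1, 0, 0, 0, 1, 1],
            [0, 1, 0, 0, 0, 0, 1, 1],
        ],
        dtype=np.uint8,
    )
    pos = np.array([100, 250, 400, 500, 720, 810, 905, 990], dtype=np.int64)
    return PhasedPanel(H, pos, pos / 1e6)


@pytest.fixture
def small_sites(small_panel):
    return build_site_table(small_panel)
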