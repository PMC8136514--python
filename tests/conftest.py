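import numpy as np
import pytest

from gv1scan import synthetic
from gv1scan.cnv import DepthProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_panel_profiles():
    """Depth profiles for the default strain panel, Poisson noise, seed 7."""
    cfg = synthetic.SimConfig(region=synthetic.PANEL_REGION, window_bp=10_000, seed=7)
    return synthetic.gen_depth_profiles(synthetic.default_strain_panel(), cfg)


@pytest.fixture
def flat_profile_pair():
    """Two identical noise-free diploid profiles on a tiny grid."""
    starts = np.arange(0, 100_000, 10_000)
    ends = starts + 10_000
    counts = np.full(10, 100.0)
    mk = lambda name: DepthProfile(name, "13", starts, ends, counts.copy(), library_size=1000.0)
    return mk("s1"), mk("s2")


@pytest.fixture
def small_backcross():
    """Fully penetrant 500-animal backcross with the trait at marker M3."""
    markers = [("M1", 63.0, 31.5), ("M2", 64.0, 32.0), ("M3", 65.0, 32.5),
               ("M4", 66.0, 33.0), ("M5", 67.0, 33.5)]
    return synthetic.gen_backcross(markers, trait_pos_cm=32.5, n_animals=500,
                                   penetrance=1.0, seed=11)
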