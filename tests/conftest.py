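import numpy as np
import pytest

import petfda as pf


@pytest.fixture(scope="session")
def gamma_aif():
    """Default scaled-gamma arterial input on [0, 2000] s."""
    return pf.synthetic_input_function(tau=2000.0)


@pytest.fixture(scope="session")
def schedule32():
    """PET-style 32-frame schedule of increasing durations."""
    return pf.default_frame_schedule()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_scan(values, lam=0.0, voxel_size=1.0, mask=None, start=None, end=None):
    """Small helper: wrap an array (spatial..., p) into an X-scale scan."""
    p = values.shape[-1]
    if start is None:
        start = np.arange(p, dtype=float)
        end = start + 1.0
    sched = pf.FrameSchedule(start, end)
    return pf.DynamicScan(values, sched, lam=lam, mask=mask,
                          voxel_size=voxel_size)


@pytest.fixture()
def tiny_phantom():
    """Noise-free, blur-free single-region compartmental phantom."""
    region = pf.RegionSpec(2, 200, alphas=(0.0060,), betas=(0.0030,))
    cfg = pf.PhantomConfig(grid_shape=(16, 16), regions=[region],
                           psf_fwhm_mm=0.0, kappa=0.0, seed=11)
    return pf.simulate_phantom_scan(cfg)
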