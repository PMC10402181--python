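import numpy as np
import pytest

import relaxmore as rm


@pytest.fixture(scope="session")
def brain_acq() -> rm.AcquisitionSpec:
    """The 3T brain vFA protocol: FA {5,10,20,40} deg, TR 40 ms."""
    return rm.AcquisitionSpec([5.0, 10.0, 20.0, 40.0], 40.0)


@pytest.fixture()
def random_maps() -> rm.ParameterMaps:
    """Seeded random valid parameter maps on a small 3D grid."""
    rng = np.random.default_rng(7)
    t1 = rng.uniform(300.0, 3000.0, size=(6, 5, 2))
    i0 = rng.uniform(0.5, 1.5, size=(6, 5, 2)) * np.exp(
        1j * rng.uniform(-np.pi, np.pi, size=(6, 5, 2))
    )
    return rm.ParameterMaps(t1, i0)


@pytest.fixture(scope="session")
def tiny_instance(brain_acq):
    """8x8 single-coil 2-flip-angle instance for gradient/oracle tests."""
    rng = np.random.default_rng(11)
    grid = (8, 8, 1)
    acq = rm.AcquisitionSpec([10.0, 30.0], 40.0)
    coils = rm.simulate_coils(grid, 1, seed=3)
    mask = rm.make_cartesian_vd_mask(8, 8, 2.0, n_center=2, nk=2, seed=5)
    t1 = rng.uniform(500.0, 2000.0, size=grid)
    i0 = rng.standard_normal(grid) + 1j * rng.standard_normal(grid)
    truth = rm.ParameterMaps(t1, i0)
    x = rm.spgr_signal(truth, acq)
    f = rm.forward_encode(x, coils, mask)
    kdata = rm.KSpaceData(f, mask, coils, acq)
    return truth, kdata


@pytest.fixture(scope="session")
def small_phantom_acquisition(brain_acq):
    """24x24 brain-like phantom with 3 coils, AF=2 mask, light noise."""
    grid = (24, 24, 1)
    truth = rm.make_brain_like_phantom(grid, seed=21)
    coils = rm.simulate_coils(grid, 3, seed=22)
    mask = rm.make_cartesian_vd_mask(24, 24, 2.0, n_center=4, nk=4, seed=23)
    full, under = rm.simulate_acquisition(
        truth, coils, brain_acq, mask, noise_sigma=0.003, seed=24
    )
    return truth, coils, mask, full, under
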