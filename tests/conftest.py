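import numpy as np
import pytest

import hipkin as hk


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_geometry():
    """Desk-scale panel decimated 16x: 95x95 pixels."""
    return hk.default_geometry(downsample=16)


@pytest.fixture(scope="session")
def small_femur():
    """Coarse femur-like phantom for registration tests (48^3 at 3 mm)."""
    spec = hk.PhantomSpec(shape=(48, 48, 48), spacing=(3.0, 3.0, 3.0))
    return hk.crop_to_mask(hk.make_phantom(spec), margin=4.0)


@pytest.fixture(scope="session")
def blob_volume():
    spec = hk.PhantomSpec(kind="blob", shape=(40, 40, 40),
                          spacing=(2.0, 2.0, 2.0))
    return hk.make_phantom(spec)


@pytest.fixture(scope="session")
def fast_config():
    """Two-stage search config sized for the coarse test phantom."""
    return hk.RegistrationConfig(stages=(
        hk.Stage(downsample=2, max_evaluations=200, xtol_mm=0.05,
                 xtol_deg=0.05, simplex_step_mm=2.0, simplex_step_deg=2.0),
        hk.Stage(downsample=1, max_evaluations=200, xtol_mm=0.01,
                 xtol_deg=0.01, simplex_step_mm=0.3, simplex_step_deg=0.3),
    ))


def random_pose(rng, t_scale=20.0, r_scale=30.0):
    v = np.concatenate([rng.uniform(-t_scale, t_scale, 3),
                        rng.uniform(-r_scale, r_scale, 3)])
    return hk.Pose.from_vector(v)
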