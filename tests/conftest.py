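import numpy as np
import pytest

from ringtear.base_state import TubeGeometry, solve_radial_equilibrium
from ringtear.fundamental import derive_coefficient_functions
from ringtear.material import MaterialParams


@pytest.fixture(scope="session")
def params_ref():
    """Rabbit-carotid media constants used throughout the study."""
    return MaterialParams(c=3.0, k1=2.3632, k2=0.8393, beta=np.pi / 3)


@pytest.fixture(scope="session")
def geom_ref():
    """Reference geometry: residually-unstressed, inflated, stretched tube."""
    return TubeGeometry(r_in=4.0, r_out=6.0, r_c=5.0, R_in=3.9,
                        kappa=1.0, lam=1.1)


@pytest.fixture(scope="session")
def base_ref(geom_ref, params_ref):
    return solve_radial_equilibrium(geom_ref, params_ref)


@pytest.fixture(scope="session")
def coeffs_ref(base_ref):
    return derive_coefficient_functions(base_ref)


@pytest.fixture(scope="session")
def geom_unloaded():
    """No residual stress, no pre-stretch, reference = current."""
    return TubeGeometry(r_in=4.0, r_out=6.0, r_c=5.0, R_in=4.0,
                        kappa=1.0, lam=1.0)


def random_unimodular_diag(rng, spread=0.35):
    """Random diagonal unimodular deformation gradient."""
    from ringtear.material import DeformationGradientDiag
    a_t = float(np.exp(rng.uniform(-spread, spread)))
    a_z = float(np.exp(rng.uniform(-spread, spread)))
    return DeformationGradientDiag(1.0 / (a_t * a_z), a_t, a_z)
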