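import numpy as np
import pytest

import cnparcel as cn


@pytest.fixture(scope="session")
def scheme():
    return cn.default_scheme()


@pytest.fixture(scope="session")
def phantom():
    return cn.make_cn_phantom()


@pytest.fixture(scope="session")
def phantom_spline(phantom):
    return cn.fit_longitudinal_spline(phantom.mask, phantom.affine,
                                      phantom.ac_point,
                                      posterior_hint=phantom.arc[0])


@pytest.fixture(scope="session")
def noiseless_tensor_field(phantom, scheme):
    dwi = cn.simulate_dwi(phantom, scheme)
    return cn.fit_tensors(dwi, phantom.mask)


@pytest.fixture(scope="session")
def noiseless_profile(noiseless_tensor_field, phantom_spline):
    return cn.radiality_profile(noiseless_tensor_field, phantom_spline)


def uniform_field(shape=(20, 80, 20), axis=1):
    """Direction field pointing along one grid axis, amplitude 1."""
    dirs = np.zeros(shape + (1, 3))
    dirs[..., 0, axis] = 1.0
    amps = np.ones(shape + (1,))
    return cn.DirectionField(directions=dirs, amplitudes=amps,
                             affine=np.eye(4))
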