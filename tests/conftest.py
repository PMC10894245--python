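import numpy as np
import pytest
from dataclasses import replace

import tcdcm as T


@pytest.fixture(scope="session")
def params():
    return T.build_default_model()


@pytest.fixture(scope="session")
def priors(params):
    return T.PriorSpec.from_model(params)


@pytest.fixture(scope="session")
def concrete(params):
    return params.evaluate()


@pytest.fixture(scope="session")
def fixed_point(concrete):
    return T.find_fixed_point(concrete)


@pytest.fixture(scope="session")
def coarse_freqs():
    """Reduced 3-Hz grid used to keep inversion-heavy tests quick."""
    return np.arange(4.0, 91.0, 3.0)


@pytest.fixture(scope="session")
def default_csd(concrete):
    return T.predict_csd(concrete)


def make_zero_coupling(params, extrinsic_only=False, common_noise=True):
    """A copy of the model with intrinsic and/or extrinsic gains set to zero
    (a zero prior mean pins theta = 0 regardless of the latent)."""
    specs = []
    for s in params.specs:
        zero_ext = s.name.startswith("ext_")
        zero_int = s.name.startswith("g_") and not extrinsic_only
        if zero_ext or zero_int:
            specs.append(replace(s, mean=0.0))
        elif s.name == "alpha_c" and not common_noise:
            specs.append(replace(s, mean=0.0))
        else:
            specs.append(s)
    return T.TCMParameters(nodes=params.nodes, specs=tuple(specs),
                           constants=dict(params.constants))


@pytest.fixture(scope="session")
def zero_coupling(params):
    return make_zero_coupling(params)
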