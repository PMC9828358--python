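import numpy as np
import pytest

from tyrspec import reference as ref
from tyrspec.simulate import DecaySimSpec, gen_tcspc_decay


@pytest.fixture(scope="session")
def decay_100um_noiseless():
    """Noiseless three-exponential decay built from the literature 100 uM
    NLLS parameters, Gaussian IRF."""
    taus, fractions = ref.NLLS_TABLE[100]
    spec = DecaySimSpec.from_fractional_intensities(taus, fractions, noise="none")
    decay, irf = gen_tcspc_decay(spec)
    return spec, decay, irf


@pytest.fixture(scope="session")
def mem_100um_noiseless():
    """Noiseless decay built from the literature 100 uM MEM band parameters
    (intensity fractions proportional to the tabulated weights)."""
    taus, weights = ref.MEM_TABLE[100]
    fractions = np.asarray(weights) / np.sum(weights)
    spec = DecaySimSpec.from_fractional_intensities(taus, fractions, noise="none")
    decay, irf = gen_tcspc_decay(spec)
    return spec, decay, irf
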