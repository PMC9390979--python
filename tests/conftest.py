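import numpy as np
import pytest

from rcnoise.calibration import frozen_context
from rcnoise.presets import default_modules, reduced_regime, strong_competition


@pytest.fixture(scope="session")
def default_rc():
    """Competitive circuit calibrated to mRNA mean 10, protein mean 100."""
    return default_modules("COMPETITIVE")


@pytest.fixture(scope="session")
def default_ur():
    return default_modules("UNLIMITED")


@pytest.fixture(scope="session")
def default_or():
    return default_modules("ORTHOGONAL")


@pytest.fixture(scope="session")
def default_frozen(default_rc):
    mods, ctx = default_rc
    return mods, frozen_context(ctx, mods)


@pytest.fixture(scope="session")
def strong_rc():
    """Strong-competition regime: J_p=2, protein mean 1000."""
    return strong_competition()


@pytest.fixture(scope="session")
def reduced_rc():
    """Small-copy regime for exact master-equation work."""
    return reduced_regime("COMPETITIVE")


def numeric_jacobian(f, x, h=1e-6):
    """Central-difference Jacobian used to cross-check analytic gradients."""
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(f(x))
    J = np.zeros((f0.size, x.size))
    for j in range(x.size):
        step = h * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += step
        xm[j] -= step
        J[:, j] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (2 * step)
    return J
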