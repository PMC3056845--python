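import numpy as np
import pytest

from mcrtsim import TrialData


@pytest.fixture
def toy_two_centres() -> TrialData:
    """Two balanced centres of 4; centre 2 is centre 1 shifted by +1.

    Closed forms: arm-mean difference 1.0 in both centres; pooled two-sample
    t-test se = sqrt(10/12); within-centre (fixed-intercept) fit has
    residual df 5 and se = sqrt(1.6 * 0.5).
    """
    centre = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    arm = np.array([0, 0, 1, 1, 0, 0, 1, 1])
    y = np.array([0.0, 2.0, 1.0, 3.0, 1.0, 3.0, 2.0, 4.0])
    return TrialData(centre, arm, y)


@pytest.fixture
def toy_one_centre() -> TrialData:
    """Single centre, control {0, 2, 1, 3} and treatment {1, 3, 2, 4}."""
    centre = np.ones(8, dtype=int)
    arm = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    y = np.array([0.0, 2.0, 1.0, 3.0, 1.0, 3.0, 2.0, 4.0])
    return TrialData(centre, arm, y)
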