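import numpy as np
import pytest

from growthscore import GrowthCurve, GrowthParameters, logistic


@pytest.fixture
def reference_params() -> GrowthParameters:
    """A well-behaved growing curve's parameters."""
    return GrowthParameters(y0=0.05, lag=20.0, mu=0.3, A=1.0)


@pytest.fixture
def reference_curve(reference_params) -> GrowthCurve:
    """Noise-free logistic curve on a half-hour grid over 100 h."""
    t = np.arange(0.0, 100.0 + 0.25, 0.5)
    return GrowthCurve(time=t, od=logistic(reference_params, t), well_id="A01")
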