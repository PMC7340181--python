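import numpy as np
import pytest

from pctsim import ControlUnitParams, LoopEnvironment


def draw_stable_loop(rng: np.random.Generator):
    """Random single-loop parameters inside the discrete stability region.

    The one-step coefficient of the loop is 1 - (1 + Ki*Kf*Ko)/S; draws
    enforce S > 0.7*(1 + loop gain) so the magnitude stays below ~0.43 on
    the oscillatory side while arbitrarily slow loops remain possible.
    """
    ki = rng.uniform(0.2, 2.0)
    kf = rng.uniform(0.2, 2.0)
    ko = rng.uniform(1.0, 30.0)
    loop_gain = ki * kf * ko
    slowing = max(rng.uniform(1.0, 50.0), 0.7 * (1.0 + loop_gain))
    params = ControlUnitParams(
        input_gain=ki,
        output_gain=ko,
        slowing=slowing,
        reference=rng.uniform(-5.0, 5.0),
    )
    env = LoopEnvironment(feedback_gain=kf, disturbance=rng.uniform(-3.0, 3.0))
    return params, env


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
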