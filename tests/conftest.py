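import numpy as np
import pytest

from optoclamp.plants import NetworkPlant, NetworkPlantParams, TCUPlant, TCUPlantParams


@pytest.fixture(scope="session")
def network_plant():
    """Nominal synthetic cultured network (shared; reset per use)."""
    return NetworkPlant(NetworkPlantParams(), seed=0)


@pytest.fixture(scope="session")
def fixed_network_plant():
    """Network plant without session-to-session excitability variation,
    for tests that check calibrated mean rates on single seeds."""
    return NetworkPlant(NetworkPlantParams(session_cv=1e-9), seed=0)


@pytest.fixture(scope="session")
def tcu_plant():
    return TCUPlant(TCUPlantParams(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


class StaticGainPlant:
    """Deterministic linear test plant: population rate = gain * U_C.

    Emits integer spike counts whose running total matches the commanded
    rate exactly (fractional spikes are carried over), so classical linear
    control theory applies without stochastic slack.  Pair it with a PI
    controller using the ``continuous`` waveform, whose blue power is
    13.4 * U_C, so U_C is recovered exactly from the light trace.
    """

    def __init__(self, gain: float = 10.0, n_units: int = 10):
        self.gain = gain
        self.n_units = n_units
        self.params = None
        self.reset(0)

    def reset(self, seed: int) -> None:
        self.seed = seed
        self._carry = 0.0

    def step(self, blue_power: float, yellow_power: float, dt: float):
        rate = self.gain * (blue_power / 13.4)
        expected = rate * self.n_units * dt + self._carry
        emit = int(expected)
        self._carry = expected - emit
        counts = np.zeros(self.n_units, dtype=int)
        counts[: min(emit, self.n_units)] = 1
        if emit > self.n_units:
            counts += (emit - self.n_units) // self.n_units
        return counts


@pytest.fixture()
def static_gain_plant():
    return StaticGainPlant()
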