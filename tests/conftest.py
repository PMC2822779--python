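import numpy as np
import pytest

from tailbeat.trace import BilateralTrace, make_time_grid


def circular_diff(a: float, b: float) -> float:
    """Distance between two phases on the unit circle (cycles)."""
    return abs(((a - b + 0.5) % 1.0) - 0.5)


def sine_pair(
    freq_hz: float,
    delay_frac: float,
    rate_hz: float = 500.0,
    n: int = 5000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BilateralTrace:
    """Left = sine, right = left delayed by ``delay_frac`` of a period."""
    t = make_time_grid(n, rate_hz)
    rng = np.random.default_rng(seed)
    left = np.sin(2 * np.pi * freq_hz * t)
    right = np.sin(2 * np.pi * freq_hz * (t - delay_frac / freq_hz))
    if noise_sd > 0:
        left = left + rng.normal(0, noise_sd, n)
        right = right + rng.normal(0, noise_sd, n)
    return BilateralTrace(t=t, left=left, right=right, rate_hz=rate_hz)


@pytest.fixture(scope="session")
def intact_trace():
    """One short intact-preset trace, shared across tests."""
    from tailbeat.synth import preset, simulate_cpg

    params = preset("intact").params.replace(duration_s=8.0, seed=1)
    tr = simulate_cpg(params)
    tr.condition = "intact"
    return tr


@pytest.fixture(scope="session")
def strychnine_trace():
    from tailbeat.synth import preset, simulate_cpg

    params = preset("strychnine").params.replace(duration_s=15.0, seed=1)
    tr = simulate_cpg(params)
    tr.condition = "strychnine"
    return tr
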