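import numpy as np
import pytest

from teamneuro import GroundTruthEpoch, SynthConfig, generate_power_tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def epoch_config():
    """Small single-stream config with a full-occupancy high-power epoch."""
    return SynthConfig(
        n_members=3,
        sensors=("Cz",),
        bins=(10,),
        duration_s=600,
        seed=7,
        epochs=(
            GroundTruthEpoch(member=0, interval=(300, 400), forced_level=3),
        ),
    )


@pytest.fixture
def epoch_tensor(epoch_config):
    tensor, truth = generate_power_tensor(epoch_config)
    return tensor, truth


def window_entropy_oracle(symbols, window, missing=-1):
    """Independent count-based sliding entropy: brute-force Counter per window.

    Returns NaN during warm-up and where >20% of the window is missing.
    """
    from collections import Counter
    import math

    T = len(symbols)
    out = np.full(T, np.nan)
    for t in range(window - 1, T):
        win = [s for s in symbols[t - window + 1 : t + 1] if s != missing]
        if window - len(win) > 0.2 * window or not win:
            continue
        n = len(win)
        out[t] = -sum(
            (c / n) * math.log2(c / n) for c in Counter(win).values()
        )
    return out
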