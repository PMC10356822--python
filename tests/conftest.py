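import numpy as np
import pytest

from spikegrid import SceneConfig, SpikeTrain, TrialSet

T = 3.0


def poisson_train(rng, rate=10.0, duration=T) -> SpikeTrain:
    n = rng.poisson(rate * duration)
    return SpikeTrain(np.sort(rng.uniform(0.0, duration, n)), duration)


def poisson_set(rng, target_id=1, rate=10.0, n_trials=10, duration=T) -> TrialSet:
    return TrialSet(
        unit_id="u0",
        condition="control",
        target_id=target_id,
        scene=SceneConfig(target_loc=0),
        trials=[poisson_train(rng, rate, duration) for _ in range(n_trials)],
    )


def pattern_set(times, target_id=1, n_trials=10, duration=T) -> TrialSet:
    """n identical copies of one deterministic spike pattern."""
    train = SpikeTrain(np.asarray(times, dtype=float), duration)
    return TrialSet(
        unit_id="u0",
        condition="control",
        target_id=target_id,
        scene=SceneConfig(target_loc=0),
        trials=[train] * n_trials,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
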