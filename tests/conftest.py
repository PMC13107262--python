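import numpy as np
import pytest

from codactivity import (
    BehaviorSpec,
    ScenarioConfig,
    FishMeta,
    ReceiverSpec,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study():
    """A small two-receiver spawning study with echoes and spurious hits."""
    t0 = 1.6121376e9  # 2021-02-01 UTC
    days = 4
    fish = tuple(
        FishMeta(f"X{i}", "F" if i % 2 == 0 else "M", 60.0 + i, 2021, "testground", t0)
        for i in range(6)
    )
    receivers = (
        ReceiverSpec("A", t0 - 86400, t0 + (days + 2) * 86400, drift_total=20.0, detect_prob=0.8),
        ReceiverSpec("B", t0 - 86400, t0 + (days + 2) * 86400, drift_total=-12.0, detect_prob=0.6),
    )
    scenario = ScenarioConfig(
        name="small",
        fish=fish,
        receivers=receivers,
        behavior=BehaviorSpec(),
        t0=t0,
        t_end=t0 + days * 86400,
        spurious_per_day=2.0,
    )
    return simulate_study(scenario, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
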