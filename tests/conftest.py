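import numpy as np
import pytest

from lenspol import (
    GroupSpec,
    LikertScheme,
    OpinionWave,
    ScenarioSpec,
    build_lens_set,
    generate_scenario,
    two_lenses_scenario,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_wave():
    """Four respondents, two groups, unit weights, 2 items."""
    return OpinionWave(
        wave_label="w1",
        opinions=np.array([[0.1, 0.2], [0.2, 0.1], [0.8, 0.9], [0.9, 0.8]]),
        identities=["A", "A", "B", "B"],
        weights=np.ones(4),
        item_names=["q1", "q2"],
    )


@pytest.fixture
def two_lenses_waves():
    scenario = two_lenses_scenario(n_per_group=300, seed=11)
    return generate_scenario(scenario)[0]


def random_wave(rng, n=40, m=2, n_groups=2, label="w"):
    """Random multi-group wave used by property tests."""
    groups = [f"g{k}" for k in range(n_groups)]
    specs = tuple(
        GroupSpec(
            label=g,
            n=n // n_groups,
            mean=tuple(rng.uniform(0.3, 0.7, size=m)),
            covariance=_random_cov(rng, m, scale=0.05),
        )
        for g in groups
    )
    scenario = ScenarioSpec(waves=((label, specs),), seed=int(rng.integers(2**31)))
    return generate_scenario(scenario)[0]


def _random_cov(rng, m, scale=0.1):
    a = rng.normal(size=(m, m)) * scale
    return a @ a.T + np.eye(m) * scale**2


@pytest.fixture
def likert5():
    return LikertScheme()
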