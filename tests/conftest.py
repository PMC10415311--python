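import numpy as np
import pytest

from mitonet import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-structure cohort shared by read-only tests."""
    config = synthetic.SyntheticConfig(n_per_group=6, seed=11)
    return synthetic.generate_cohort(config)


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong planted block structure for recovery tests."""
    config = synthetic.SyntheticConfig(
        n_per_group=20, within_block_r=0.9, between_block_r=0.0,
        missing_rate=0.0, seed=5)
    return synthetic.generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def enumerate_set_partitions(items):
    """All set partitions of ``items`` (independent oracle helper)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in enumerate_set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition
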