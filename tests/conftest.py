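import numpy as np
import pytest

from sexratio import ConceptionCycle, CycleDataset, GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


def make_cycle(i=0, sex=0, days=(0,), foll_len=15, study=None):
    """A valid cycle with intercourse on the given relative days (-8..3)."""
    ic = [0] * 12
    for d in days:
        ic[d + 8] = 1  # day -8 -> column 0, day 0 -> column 8
    return ConceptionCycle(
        woman_id=f"W{i:04d}",
        cycle_id=f"C{i:04d}",
        sex=sex,
        intercourse=tuple(ic),
        follicular_length=foll_len,
        study_label=study,
    )


@pytest.fixture
def tiny_dataset():
    """Six hand-built cycles spanning sexes, classes and studies."""
    return CycleDataset(
        [
            make_cycle(0, sex=0, days=(0,), foll_len=12, study="EU"),
            make_cycle(1, sex=1, days=(-2, 0), foll_len=15, study="EU"),
            make_cycle(2, sex=0, days=(-8, 3), foll_len=18, study="IT"),
            make_cycle(3, sex=1, days=(1,), foll_len=22, study="IT"),
            make_cycle(4, sex=0, days=(-1, 0, 1), foll_len=13, study="NZ"),
            make_cycle(5, sex=1, days=(-4,), foll_len=16, study="NZ"),
        ]
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A reproducible 60-cycle synthetic dataset at the default conditions."""
    return generate_dataset(GeneratorConfig(n_cycles=60, seed=7))
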