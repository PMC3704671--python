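import pytest

import mvpasim as m


@pytest.fixture(scope="session")
def design160():
    """Canonical 160-volume design: 5 reps/class, 16 volumes/block."""
    return m.ExperimentDesign()


@pytest.fixture(scope="session")
def design480():
    """480-volume design: 15 reps/class."""
    return m.ExperimentDesign(reps_per_class=15)


@pytest.fixture(scope="session")
def tiny_design():
    """Smallest interesting design: 3 reps, 4 volumes/block, trim 2."""
    return m.ExperimentDesign(tr_seconds=2.0, block_seconds=8.0,
                              volumes_per_block=4, reps_per_class=3,
                              trim_volumes=2)


@pytest.fixture(scope="session")
def null_ts(design160):
    """One trimmed null BOLD dataset, 16 voxels."""
    return m.simulate_dataset(design160, 16, seed=101)
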