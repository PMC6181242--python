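import numpy as np
import pytest

from nirsreject.design import BlockDesign, EpochSet


@pytest.fixture
def design():
    return BlockDesign()


@pytest.fixture
def epoch_times(design):
    n_pre = int(round(design.pre_s / 0.1))
    n_total = design.epoch_n_samples(0.1)
    return (np.arange(n_total) - n_pre) * 0.1


def make_epoch_set(values, design=None, times=None):
    """Wrap an (n_epochs, n_times) array into an EpochSet on the 0.1-s grid."""
    design = design or BlockDesign()
    values = np.asarray(values, dtype=float)
    if times is None:
        n_pre = int(round(design.pre_s / 0.1))
        times = (np.arange(values.shape[1]) - n_pre) * 0.1
    return EpochSet(design=design, channel="CH1", signal_type="O2Hb",
                    times=times, values=values)


@pytest.fixture
def epoch_set_factory():
    return make_epoch_set
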