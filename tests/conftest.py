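import numpy as np
import pytest

from sleepmicro import synth

FS = 200.0


@pytest.fixture(scope="session")
def quiet_background():
    """10 min of zero-amplitude background (event-only test bed)."""
    return synth.make_background(
        synth.BackgroundSpec(n_channels=1, duration=600.0, rms=0.0, seed=101)
    )


@pytest.fixture(scope="session")
def pink_background():
    """10 min of 1/f^1.5 background at 20 µV rms."""
    return synth.make_background(
        synth.BackgroundSpec(
            n_channels=1, duration=600.0, rms=20.0, one_over_f_slope=1.5, seed=102
        )
    )


@pytest.fixture(scope="session")
def so_recording(quiet_background):
    """SO train (−60/+50 µV) on quiet background, with ground truth."""
    rec, truth = synth.inject_so(
        quiet_background,
        synth.SOSpec(density=5.0, neg_peak_amp=-60.0, pos_peak_amp=50.0),
        seed=7,
    )
    return rec, truth


def full_mask(rec):
    return np.ones(rec.n_samples, dtype=bool)
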