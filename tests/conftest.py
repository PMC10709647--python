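import numpy as np
import pytest

from eegfc.recording import GROUP_UNKNOWN, Recording
from eegfc.simulate import default_config, generate_cohort

FS = 250.0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_recording(data, fs=FS, labels=None, intervals=None,
                   group=GROUP_UNKNOWN, subject_id="S1"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    if intervals is None:
        intervals = [(0.0, data.shape[1] / fs)]
    return Recording(subject_id=subject_id, group_label=group,
                     channel_labels=list(labels), fs=fs, data=data,
                     eyes_closed_intervals=list(intervals))


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny default-preset cohort (4 + 4 subjects, 12 s) shared across tests."""
    return generate_cohort(default_config(n_per_group=4, duration_s=12.0, seed=5))


@pytest.fixture(scope="session")
def cohort_subject(small_cohort):
    return small_cohort[0]
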