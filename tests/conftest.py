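"""Shared fixtures: small synthetic datasets at the analysis rate.

Everything is generated at run time; the sizes are deliberately small so the
full suite stays fast while still exercising every stage end-to-end.
"""

import numpy as np
import pytest

from pausetrack import CVPlan, LagSpec, SimConfig, segments_from_records, simulate_segment


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale cohort configuration: envelope and EEG directly at the
    128 Hz analysis rate, 4 channels, ~25 s natural segments."""
    return SimConfig(n_subjects=2, n_segments_per_condition=4, n_channels=4,
                     fs_eeg=128.0, fs_env=128.0, n_words_per_segment=60,
                     onset_gain=5.0, sustained_gain=1.0, snr_db=5.0, seed=11)


@pytest.fixture(scope="session")
def short_records(small_config):
    """Four short-pause segments for subject 0."""
    return [simulate_segment(small_config, "short", 0, s) for s in range(4)]


@pytest.fixture(scope="session")
def delta_segments(short_records):
    return segments_from_records(short_records, "delta")


@pytest.fixture(scope="session")
def delta_plan(delta_segments):
    return CVPlan(segments=delta_segments, lag_spec=LagSpec(0, 300, 128),
                  subject="S00", condition="short", band="delta")
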