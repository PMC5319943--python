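import numpy as np
import pytest

from ecgverify import (NoiseSpec, bandpass_filter, make_subject,
                       synthesize_record)


@pytest.fixture(scope="session")
def clean_record():
    """One noiseless 60 s subject record at 200 Hz."""
    template = make_subject(0)
    return synthesize_record(template, 60.0, 200.0, NoiseSpec.clean(),
                             abnormal_fraction=0.0, seed=100)


@pytest.fixture(scope="session")
def filtered_clean_record(clean_record):
    return bandpass_filter(clean_record)


@pytest.fixture(scope="session")
def genuine_beat_matrix(filtered_clean_record):
    """Segmented beats of the clean record (truth-aligned)."""
    from ecgverify import segment_heartbeats

    rec = filtered_clean_record
    half = int(rec.fs) // 2
    peaks = [r for r in rec.truth_r
             if half <= r <= len(rec.samples) - half]
    return segment_heartbeats(rec, np.asarray(peaks))
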