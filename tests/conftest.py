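"""Shared fixtures: synthetic records and segment datasets, generated once."""

import numpy as np
import pytest

from msapnea import (SegmentDataset, SynthConfig, bandpass, detect_r_peaks,
                     generate_record, preprocess_record)


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 8-minute record with a 50/50 label mix, plus its truth."""
    cfg = SynthConfig(n_minutes=8, apnea_fraction=0.5, seed=11).noise_free()
    return generate_record(cfg)


@pytest.fixture(scope="session")
def noisy_record():
    """Same RR/label process as ``clean_record`` but with default noise."""
    cfg = SynthConfig(n_minutes=8, apnea_fraction=0.5, seed=11)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def clean_peaks(clean_record):
    record, _ = clean_record
    return detect_r_peaks(bandpass(record))


@pytest.fixture(scope="session")
def small_dataset():
    """Four 10-minute records, half apneic minutes, full pipeline."""
    parts = []
    for i in range(4):
        record, _ = generate_record(
            SynthConfig(n_minutes=10, apnea_fraction=0.5, seed=100 + i))
        record.record_id = f"rec{i}"
        parts.append(preprocess_record(record))
    return SegmentDataset.concatenate(parts)


def match_peaks(true_times, detected_times, tol=0.02):
    """Greedy one-to-one matching; returns (recall, precision)."""
    true_times = np.asarray(true_times)
    detected_times = np.asarray(detected_times)
    used = np.zeros(len(detected_times), dtype=bool)
    tp = 0
    for t in true_times:
        if len(detected_times) == 0:
            break
        d = np.abs(detected_times - t)
        d[used] = np.inf
        i = int(np.argmin(d))
        if d[i] <= tol:
            used[i] = True
            tp += 1
    recall = tp / max(len(true_times), 1)
    precision = tp / max(len(detected_times), 1)
    return recall, precision
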