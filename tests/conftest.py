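import numpy as np
import pytest

from mi_ecgkit import synthetic as syn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_record():
    """Ten noiseless healthy beats at 1 kHz."""
    cfg = syn.RecordConfig(n_beats=10, fs=1000.0, rr_jitter_sd=0.02, seed=42)
    return syn.make_record(cfg, ["H"] * 10)


@pytest.fixture(scope="session")
def noisy_record():
    cfg = syn.RecordConfig(n_beats=10, fs=1000.0, rr_jitter_sd=0.02,
                           noise_sd=0.02, baseline_amp=0.1, seed=42)
    return syn.make_record(cfg, ["H"] * 10)


@pytest.fixture(scope="session")
def all_class_records():
    """One noiseless 20-beat record per class (200 beats total)."""
    out = {}
    for lab in syn.CLASS_LABELS:
        cfg = syn.RecordConfig(n_beats=20, fs=1000.0, rr_jitter_sd=0.02,
                               seed=7)
        out[lab] = syn.make_record(cfg, [lab] * 20)
    return out
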