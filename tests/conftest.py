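import numpy as np
import pytest

from bcgsleep import SimulationConfig, simulate_recording


@pytest.fixture(scope="session")
def clean_recording():
    """A 10-min artifact-free recording with a well-coupled sensor."""
    cfg = SimulationConfig(duration_s=600.0, seed=11)
    return cfg, simulate_recording(cfg)


@pytest.fixture(scope="session")
def regime_recording():
    """One recording under the idealised apnea-detection conditions."""
    cfg = SimulationConfig.apnea_oracle_regime(duration_s=7200.0, seed=4)
    return cfg, simulate_recording(cfg)


def make_record_with_window_sds(sds, window_len_s=10.0, fs=50.0):
    """A signal whose non-overlapping windows have prescribed sample SDs.

    Each window is an alternating +/-c pattern with zero mean; c is set
    so the n-1 sample SD equals the target exactly.
    """
    n = int(window_len_s * fs)
    segs = []
    for sd in sds:
        c = sd * np.sqrt((n - 1) / n)
        seg = np.tile([c, -c], n // 2)
        segs.append(seg)
    from bcgsleep import SignalRecord

    return SignalRecord(samples=np.concatenate(segs), fs=fs)
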