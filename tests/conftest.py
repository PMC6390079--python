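import numpy as np
import pytest

import affectp300 as ap


@pytest.fixture(scope="session")
def default_config():
    return ap.SimConfig(seed=1)


@pytest.fixture(scope="session")
def subject_epochs(default_config):
    """Preprocessed full 50-run EpochSet of one simulated subject."""
    runs = ap.generate_subject_recording(default_config, 0)
    return ap.preprocess_subject(runs)


@pytest.fixture(scope="session")
def noise_free_run():
    """One run generated without noise, with its config."""
    cfg = ap.SimConfig(noise_sd=0.0, subject_amp_range=(1.0, 1.0),
                       subject_latency_jitter_ms=0.0, seed=3)
    rec, ev = ap.generate_run(cfg, 0, 0)
    return cfg, rec, ev


def random_epochset(rng, n_epochs=8, n_channels=2, n_times=16,
                    sample_rate=256.0, channels=None):
    """Small EpochSet with arbitrary labels for unit tests."""
    import pandas as pd
    from affectp300.preprocess import EpochSet

    channels = channels or tuple(f"ch{i}" for i in range(n_channels))
    times = np.arange(n_times) / sample_rate * 1000.0
    info = pd.DataFrame({
        "stimulus_id": rng.integers(1, 3, n_epochs),
        "is_target": rng.integers(0, 2, n_epochs).astype(bool),
        "run_id": 1, "session_id": 1, "part_id": 1,
        "sequence_index": 1, "rejected": False, "zeroed": False,
    })
    return EpochSet(data=rng.normal(size=(n_epochs, len(channels), n_times)),
                    times=times, channels=channels, info=info)
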