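import numpy as np
import pytest

from somnarch import Hypnogram, SimulationConfig, synthesize_signals


@pytest.fixture(scope="session")
def nrem_block_recording():
    """30 min of pure NREMS with spindles at 2/min, gain 5 — the spindle
    recovery scenario.  Session-scoped: the signal is reused read-only."""
    cfg = SimulationConfig(duration_h=0.5, spindle_rate=2.0,
                           spindle_amp_gain=5.0, artifact_rate=0.0)
    labels = np.full(cfg.n_epochs, "N")
    recording, truth = synthesize_signals(labels, cfg, seed=42)
    hypnogram = Hypnogram(labels=labels, epoch_s=cfg.epoch_s)
    return cfg, recording, hypnogram, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_hypnogram(tokens, epoch_s=4.0, zt_start=0.0):
    return Hypnogram(labels=np.array(list(tokens), dtype="<U1"),
                     epoch_s=epoch_s, zt_start=zt_start)
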