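import numpy as np
import pytest

from codaspec.synth import DatasetConfig, plan_dataset, render_plan


@pytest.fixture(scope="session")
def small_dataset():
    """A small rendered dataset shared by read-only tests: 12 codas at 48 kHz,
    30 dB SNR, level trajectories, default a/i mixture."""
    config = DatasetConfig(whales={"ALPHA": 6, "BRAVO": 6}, sample_rate_hz=48_000.0,
                           snr_db=30.0)
    plan = plan_dataset(config, seed=7)
    recording, codas, truths = render_plan(plan, config, seed=7)
    return {
        "config": config,
        "plan": plan,
        "recording": recording,
        "codas": codas,
        "truths": {t.coda_id: t for t in truths},
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
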