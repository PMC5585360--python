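import numpy as np
import pytest

from tvcgnet import SyntheticBeatConfig, generate_record
from tvcgnet.pipeline import beats_from_record


def make_corpus(n_patients, beats_per_patient, seed, config):
    """One record per synthetic patient with a mixed N/S/V beat sequence."""
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_patients):
        seq = list(rng.choice(["N", "S", "V"], size=beats_per_patient,
                              p=[0.7, 0.15, 0.15]))
        rec_seed = int(rng.integers(2**31 - 1))
        records.append(generate_record(config, seq, rec_seed,
                                       record_id=f"p{k:03d}"))
    return records


@pytest.fixture(scope="session")
def default_config():
    return SyntheticBeatConfig()


@pytest.fixture(scope="session")
def clean_config():
    """No noise, no wander, no per-patient jitter: amplitudes are exact."""
    return SyntheticBeatConfig(noise_sd_mV=0.0, baseline_wander_amp_mV=0.0,
                               morphology_jitter_sd=0.0)


@pytest.fixture(scope="session")
def small_corpus(default_config):
    return make_corpus(4, 40, seed=7, config=default_config)


@pytest.fixture(scope="session")
def sample_beats(small_corpus, default_config):
    return beats_from_record(small_corpus[0], synthetic_config=default_config)


@pytest.fixture(scope="session")
def n_beat(sample_beats):
    """One normal beat away from the record edges."""
    for b in sample_beats[2:-2]:
        if b.label == "N":
            return b
    raise RuntimeError("no interior N beat in fixture corpus")
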