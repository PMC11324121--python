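import numpy as np
import pytest

from ecgmae.ecg_io import ECGRecord
from ecgmae.model import DecoderConfig, EncoderConfig, MAEModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_record(rng):
    return ECGRecord(
        record_id="R0",
        patient_id="P0",
        acquisition_date=None,
        signal=rng.normal(size=(12, 5000)),
    )


@pytest.fixture(scope="session")
def micro_model():
    """A very small MAE for shape/contract tests (fast to build and run)."""
    enc = EncoderConfig("micro", embed_dim=32, depth=2, n_heads=2)
    dec = DecoderConfig(embed_dim=16, depth=1, n_heads=2)
    return MAEModel(enc, dec, seed=0)
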