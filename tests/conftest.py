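import numpy as np
import pandas as pd
import pytest

from vigortrend.cohort import EpochSeries


@pytest.fixture
def make_series():
    """Factory for 60-s EpochSeries anchored at midnight."""

    def _make(counts, participant_id="p0", start="2005-03-01", epoch_length=60):
        return EpochSeries(
            participant_id=participant_id,
            start_clock=pd.Timestamp(start),
            epoch_length=epoch_length,
            counts=np.asarray(counts, dtype=np.int64),
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
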