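import datetime as dt

import pytest

from strandphen import StrandingRecord, SyntheticConfig


@pytest.fixture
def rec():
    """Factory for stranding records with sensible defaults."""
    def _make(year=2000, month=8, day=15, sex="M", age_class="mature",
              cause="shark"):
        return StrandingRecord(dt.date(year, month, day), sex, age_class, cause)
    return _make


@pytest.fixture
def small_config():
    """A one-bin synthetic configuration with a tight mid-year season."""
    return SyntheticConfig(
        seed=7, n_bins=1,
        cell_counts={(0, "M", "mature", "shark"): 20,
                     (0, "F", "mature", "shark"): 10,
                     (0, "M", "immature", "other"): 15,
                     (0, "F", "immature", "other"): 15},
        season_center={0: 240.0}, season_width80={0: 60.0},
    )
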