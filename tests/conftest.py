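import numpy as np
import pandas as pd
import pytest

from pelagic_sync.mhw import Climatology, SSTSeries, N_DOY


def flat_climatology(seas: float = 10.0, margin: float = 1.0) -> Climatology:
    """Constant climatology: seas_mean everywhere, threshold seas + margin."""
    return Climatology(
        doy=np.arange(1, N_DOY + 1),
        seas_mean=np.full(N_DOY, seas),
        thresh90=np.full(N_DOY, seas + margin),
        baseline=(2000, 2010),
        window_halfwidth=5,
        smooth_width=1,
    )


def make_series(sst, start="2015-01-01", cell_id="c0") -> SSTSeries:
    sst = np.asarray(sst, dtype=float)
    dates = pd.date_range(start, periods=len(sst), freq="D")
    return SSTSeries(dates=dates, sst=sst, cell_id=cell_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
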