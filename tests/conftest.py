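import numpy as np
import pytest

from allpx.localization import Spectrum


@pytest.fixture
def make_spectrum():
    """Factory for small constructed spectra."""

    def _make(mzs, intensities=None, *, scan_id="scan", precursor_mz=500.0,
              precursor_charge=2, fragmentation="HCD"):
        mzs = np.asarray(mzs, dtype=float)
        if intensities is None:
            intensities = np.full(mzs.shape, 100.0)
        return Spectrum(
            scan_id=scan_id,
            precursor_mz=precursor_mz,
            precursor_charge=precursor_charge,
            fragmentation=fragmentation,
            mz=mzs,
            intensity=np.asarray(intensities, dtype=float),
        )

    return _make
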