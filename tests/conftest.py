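import numpy as np
import pytest

from fdomlink.eem import EEM, AbsorbanceSpectrum


@pytest.fixture
def small_eem():
    """5×4 EEM with distinct values per cell."""
    ex = np.array([250.0, 300.0, 350.0, 400.0])
    em = np.array([300.0, 350.0, 400.0, 450.0, 500.0])
    intensity = np.arange(20, dtype=float).reshape(5, 4) + 1.0
    return EEM(sample_id="s1", ex_nm=ex, em_nm=em, intensity=intensity)


@pytest.fixture
def flat_absorbance():
    wl = np.arange(230.0, 801.0)
    return AbsorbanceSpectrum(sample_id="a1", wl_nm=wl,
                              absorbance=np.zeros(wl.size))


def make_eem(ex, em, intensity, sample_id="s", **kw):
    return EEM(sample_id=sample_id, ex_nm=np.asarray(ex, dtype=float),
               em_nm=np.asarray(em, dtype=float),
               intensity=np.asarray(intensity, dtype=float), **kw)
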