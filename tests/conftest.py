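import numpy as np
import pytest

from xldoublet.chem import load_crosslinker
from xldoublet.spectra import Spectrum


@pytest.fixture(scope="session")
def uccl():
    return load_crosslinker("UCCL")


@pytest.fixture(scope="session")
def dsso():
    return load_crosslinker("DSSO")


@pytest.fixture(scope="session")
def dsbu():
    return load_crosslinker("DSBU")


@pytest.fixture
def make_spectrum():
    def _make(mz, intensity=None, precursor_mz=500.0, precursor_charge=3, **kw):
        mz = np.asarray(mz, float)
        if intensity is None:
            intensity = np.full(mz.shape, 100.0)
        return Spectrum(
            mz=mz,
            intensity=np.asarray(intensity, float),
            precursor_mz=precursor_mz,
            precursor_charge=precursor_charge,
            **kw,
        )

    return _make


@pytest.fixture
def random_spectrum():
    def _make(rng, n_peaks=100, mz_range=(150.0, 1800.0), **kw):
        mz = np.sort(rng.uniform(*mz_range, size=n_peaks))
        intensity = np.exp(rng.normal(4.0, 1.5, size=n_peaks))
        return Spectrum(
            mz=mz,
            intensity=intensity,
            precursor_mz=kw.pop("precursor_mz", 800.0),
            precursor_charge=kw.pop("precursor_charge", 3),
            **kw,
        )

    return _make
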