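import numpy as np
import pytest

from cohnet import (
    CONDITIONS,
    AcquisitionConfig,
    SpectralConfig,
    build_trial_design,
)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def spectral_cfg():
    return SpectralConfig()


@pytest.fixture(scope="session")
def default_design(acq):
    return build_trial_design(acq, CONDITIONS["ACCD"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_cm(values, labels=None, band=(0.15, 0.33), normalized=False):
    """Symmetric zero-diagonal ConnectivityMatrix from upper-triangle values."""
    from cohnet import ConnectivityMatrix

    values = np.asarray(values, float)
    n = values.shape[0]
    if labels is None:
        labels = tuple(f"R{i}" for i in range(n))
    sym = np.triu(values, 1)
    sym = sym + sym.T
    return ConnectivityMatrix(
        values=sym, roi_labels=tuple(labels), band_hz=band, normalized=normalized
    )


def cm_from_offdiag(offdiag, labels=None, normalized=False):
    """6x6 matrix whose 15 upper-triangle entries are the given sequence."""
    offdiag = np.asarray(offdiag, float)
    n = 6
    assert offdiag.size == 15
    m = np.zeros((n, n))
    m[np.triu_indices(n, 1)] = offdiag
    return make_cm(m, labels=labels, normalized=normalized)
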