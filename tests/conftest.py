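import numpy as np
import pytest

from flimcrowd.decay import DecayHistogram, InstrumentResponse

WINDOW_NS = 50.0  # 20 MHz repetition rate
BIN_WIDTH_NS = WINDOW_NS / 512


@pytest.fixture
def irf() -> InstrumentResponse:
    """100 ps FWHM Gaussian IRF positioned 2 ns into the window."""
    return InstrumentResponse(fwhm=0.1, t0=2.0)


@pytest.fixture
def grid_edges() -> np.ndarray:
    return np.arange(513) * BIN_WIDTH_NS


def noiseless_monoexp_histogram(tau: float, n_photons: float = 1e6) -> DecayHistogram:
    """Histogram whose counts are the exact per-bin integrals of exp(-t/tau)."""
    edges = np.arange(513) * BIN_WIDTH_NS
    e = np.exp(-edges / tau)
    return DecayHistogram(edges, n_photons * (e[:-1] - e[1:]))
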