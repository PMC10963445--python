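import numpy as np
import pytest

from springshift.io_formats import AnnualSeries, RingSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def simple_rings():
    """Two short hand-built ring series with known lengths."""
    return [
        RingSeries("CFC01A", 1951, np.array([1.23, 1.10, 0.98, 1.05, 0.87])),
        RingSeries("CFC01B", 1948, np.array([2.00, 1.80, 1.60, 1.55, 1.40, 1.35,
                                             1.20, 1.10])),
    ]


@pytest.fixture
def annual_line():
    """A noiseless warming line: 0.05 degC/yr from 1961."""
    years = np.arange(1961, 2011)
    return AnnualSeries("line", years, 0.05 * (years - 1961))
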