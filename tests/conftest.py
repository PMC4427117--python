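import numpy as np
import pytest

import wavexon as wx


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def strong_gene():
    """One synthetic gene with fully deterministic codon bias."""
    return wx.generate_gene(wx.GeneSpec(codon_bias=1.0, seed=7))


@pytest.fixture
def normalized(request):
    """Helper to wrap raw values as a normalized-stage signal."""

    def make(values, seq_id="s"):
        return wx.NumericSignal(seq_id, np.asarray(values, dtype=float), "normalized")

    return make
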