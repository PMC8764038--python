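import numpy as np
import pytest

from infodemic import (
    SIFConfig,
    SIFEmbedder,
    TokenFrequencyTable,
    WordVectorTable,
)


@pytest.fixture
def toy_wv() -> WordVectorTable:
    """Hand-set 2-d vectors for a tiny health vocabulary."""
    return WordVectorTable(
        dimension=2,
        entries={
            "virus": np.array([1.0, 0.0]),
            "mask": np.array([0.0, 1.0]),
            "wash": np.array([1.0, 1.0]),
            "hands": np.array([0.5, -0.5]),
            "soap": np.array([-1.0, 0.5]),
        },
    )


@pytest.fixture
def toy_freqs() -> TokenFrequencyTable:
    """Counts summing to 100: p(virus)=0.01, p(mask)=0.09, p(wash)=0.90."""
    return TokenFrequencyTable(counts={"virus": 1, "mask": 9, "wash": 90})


@pytest.fixture
def toy_embedder(toy_wv, toy_freqs) -> SIFEmbedder:
    """Raw SIF embedder (no common-component removal) over the toy tables."""
    return SIFEmbedder(toy_wv, toy_freqs, SIFConfig(n_common_components=0))
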