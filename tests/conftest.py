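import pytest

from conjnet import spectral_network, synthdata


@pytest.fixture(scope="session")
def paper_like():
    """One study-like simulated run shared across the suite."""
    return synthdata.generate(synthdata.paper_like_config(7))


@pytest.fixture(scope="session")
def paper_like_network(paper_like):
    return spectral_network.build_network(
        paper_like.spectra,
        spectral_network.CosineParams(),
        polarities=paper_like.polarities(),
    )
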