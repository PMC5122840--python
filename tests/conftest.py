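import numpy as np
import pytest

from gbrpower import SNPPanel, build_frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_snp_panel():
    """The single-SNP metformin-interaction architecture (EAF 0.44)."""
    return SNPPanel(
        freqs=np.array([0.44]),
        beta_main=np.array([0.0]),
        beta_int=np.array([np.log(0.68)]),
    )


@pytest.fixture
def grs20_panel():
    """20 high-frequency SNPs with protective interactions."""
    rng = np.random.default_rng(7)
    k = 20
    return SNPPanel(
        freqs=rng.uniform(0.2, 0.5, k),
        beta_main=np.zeros(k),
        beta_int=-rng.uniform(0.15, 0.30, k),
    )


@pytest.fixture
def small_frame(grs20_panel):
    return build_frame(grs20_panel, 500, np.random.default_rng(42))
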