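import numpy as np
import pytest

from dmsp_sip.community import CommunityConfig, sample_community


@pytest.fixture
def small_community():
    """A deterministic 6-taxon community with one degrader per phenotype."""
    cfg = CommunityConfig(
        phenotype_proportions={
            "substrate_carbon_user": 1 / 6,
            "moiety_gas_user": 1 / 6,
            "gene_carrier_nonuser": 1 / 6,
            "nonuser": 3 / 6,
        }
    )
    return sample_community(cfg, n_taxa=6, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
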