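import random

import pytest

from wxlsurvey.synthetic_data import ClusterSpec, SyntheticConfig, generate_genome


@pytest.fixture
def rng():
    return random.Random(20230914)


@pytest.fixture
def synthetic_bundle(tmp_path):
    """One synthetic genome with two planted clusters, plus its truth."""
    cfg = SyntheticConfig(
        seed=11,
        genome_id="SYNFIX",
        genes_per_replicon=45,
        planted_clusters=(
            ClusterSpec(),  # canonical 1 WxLIP + 2 WxL
            ClusterSpec(
                composition=("WXLIP_FULL", "WXL_SMALL", "WXL_LARGE", "HBD_ONLY"),
                gaps=(2, 0, 4),
            ),
        ),
        n_spurious_hits=8,
    )
    gbk, dom, truth = generate_genome(cfg, tmp_path)
    return cfg, gbk, dom, truth
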