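import pytest

from messar import (
    build_transactions,
    chloride_loss_spec,
    generate_library,
    mine_rules,
)
from messar.feature_extraction import extract_target_features


@pytest.fixture(scope="session")
def chloride_library():
    """100 distinct compounds, 30 chlorinated, HCl-loss planted at emit=1."""
    spec = chloride_loss_spec(seed=11)
    return spec, generate_library(spec)


@pytest.fixture(scope="session")
def chloride_rules(chloride_library):
    _, lib = chloride_library
    feats = [extract_target_features(r) for r in lib.records]
    txns = build_transactions(lib, feats, ["CCl"], max_cuts=1)
    return txns, mine_rules(txns)
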