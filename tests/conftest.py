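import numpy as np
import pandas as pd
import pytest

from pdxfidelity.methylation import BetaMatrix
from pdxfidelity.synthetic import ArmSpec, CohortSpec


@pytest.fixture
def small_spec() -> CohortSpec:
    return CohortSpec(n_models=4, n_probes=500, n_genes=500, seed=7)


@pytest.fixture
def two_pair_matrix() -> BetaMatrix:
    """Two models with identical-within-pair, distinct-across-model profiles."""
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 1, 50)
    b = np.clip(a + 0.4, 0, 1)
    values = pd.DataFrame({"A-PT": a, "A-X": a, "B-PT": b, "B-X": b},
                          index=[f"cg{i}" for i in range(50)])
    pairing = pd.DataFrame([
        {"sample_id": "A-PT", "model_id": "A", "tissue": "primary"},
        {"sample_id": "A-X", "model_id": "A", "tissue": "xenograft"},
        {"sample_id": "B-PT", "model_id": "B", "tissue": "primary"},
        {"sample_id": "B-X", "model_id": "B", "tissue": "xenograft"},
    ])
    return BetaMatrix(values=values, pairing=pairing)


def make_arm_spec(**kw) -> ArmSpec:
    return ArmSpec(**kw)
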