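import numpy as np
import pytest

from lncboost.config import FeatureConfig, RunConfig
from lncboost.data_io import EntityIndex, HierarchyRecordSet, InteractionMatrix
from lncboost.gradient_boosting import GbmConfig
from lncboost.autoencoder import AeTrainConfig
from lncboost.pipeline import dataset_from_bundle
from lncboost.synthetic import SyntheticSpec, generate_bundle


@pytest.fixture
def toy_hierarchy() -> HierarchyRecordSet:
    """Chain A > B > C plus siblings X, Y under a separate root R."""
    records = {
        "A": {"a"},
        "B": {"a.b"},
        "C": {"a.b.c"},
        "X": {"r.x"},
        "Y": {"r.y"},
    }
    term_names = {"a": "A", "a.b": "B", "a.b.c": "C", "r.x": "X", "r.y": "Y"}
    return HierarchyRecordSet(records=records, term_names=term_names)


@pytest.fixture
def toy_interaction() -> InteractionMatrix:
    index = EntityIndex(diseases=["d1", "d2", "d3"], lncrnas=["l1", "l2", "l3", "l4"])
    values = np.zeros((3, 4), dtype=np.int8)
    values[0, 0] = values[0, 1] = values[1, 1] = values[2, 3] = 1
    return InteractionMatrix(values=values, index=index)


@pytest.fixture
def fast_config() -> RunConfig:
    """Down-scaled pipeline config for protocol tests (tiny encoder/booster)."""
    return RunConfig(
        autoencoder=AeTrainConfig(epochs=5, batch_size=32, latent_dim=8, seed=0),
        gbm=GbmConfig(n_trees=10),
        features=FeatureConfig(layout="FHN"),
    )


@pytest.fixture
def tiny_spec() -> SyntheticSpec:
    return SyntheticSpec(n_diseases=12, n_lncrnas=18, n_clusters=3, p_in=0.7,
                         p_out=0.02, seed=5)


@pytest.fixture
def tiny_dataset(tiny_spec):
    return dataset_from_bundle(generate_bundle(tiny_spec), negative_seed=0)


@pytest.fixture(scope="session")
def default_bundle():
    """The default planted benchmark shared by the end-to-end tests."""
    return generate_bundle(SyntheticSpec())
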