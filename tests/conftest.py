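import numpy as np
import pytest

from kgrdr.synthetic_fixtures import (
    FixtureSpec,
    make_interactions,
    make_kg,
    make_similarity_stack,
)
from kgrdr.types import InteractionMatrix, SimilarityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    return FixtureSpec(
        n_drugs=20, n_diseases=18, latent_rank=3, density=0.1,
        n_views=2, noise_sigma=0.05, redundancy_copies=1,
        kg_extra_relations=2, n_aux_entities=12, seed=0,
    )


@pytest.fixture
def small_interactions(small_spec):
    return make_interactions(small_spec)


@pytest.fixture
def small_drug_stack(small_spec):
    return make_similarity_stack(small_spec, "drugs")


@pytest.fixture
def small_kg(small_spec, small_interactions):
    return make_kg(small_spec, small_interactions)


def random_similarity(rng, n, ids=None, name="rand"):
    """Symmetric [0,1] similarity matrix with unit diagonal."""
    raw = rng.random((n, n))
    values = (raw + raw.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        ids=ids or [f"e{i}" for i in range(n)], values=values, source_name=name
    )


def tiny_interactions():
    return InteractionMatrix(
        drug_ids=["dA", "dB", "dC"],
        disease_ids=["s0", "s1", "s2", "s3"],
        values=np.array([
            [1, 0, 0, 1],
            [0, 1, 0, 0],
            [1, 0, 0, 1],
        ]),
    )
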