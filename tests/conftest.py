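import numpy as np
import pytest

from genosig.features import featurize_dataset
from genosig.io import Dataset, SequenceRecord
from genosig.mimics import MutationModel, make_pairs
from genosig.synthetic import (
    MarkovDatasetSpec,
    TemplateDatasetSpec,
    generate_markov_dataset,
    generate_template_dataset,
)


def make_dataset(seqs, labels=None, prefix="s"):
    labels = labels or [None] * len(seqs)
    return Dataset(
        [
            SequenceRecord(id=f"{prefix}{i}", seq=s, label=l)
            for i, (s, l) in enumerate(zip(seqs, labels))
        ]
    )


@pytest.fixture(scope="session")
def markov3():
    """Strong-signal 3-cluster compositional dataset (small, fast)."""
    spec = MarkovDatasetSpec(n_clusters=3, seqs_per_cluster=60, seq_length=1000, seed=5)
    return generate_markov_dataset(spec)


@pytest.fixture(scope="session")
def markov3_features(markov3):
    return featurize_dataset(markov3, k=4)


@pytest.fixture(scope="session")
def markov3_pairs(markov3):
    return make_pairs(markov3, MutationModel(), n_mimics=2, k=4, seed=11)


@pytest.fixture(scope="session")
def template_small():
    """Small template-and-copies dataset at identity 0.85."""
    spec = TemplateDatasetSpec(
        n_templates=8,
        template_length=1000,
        copies_min=15,
        copies_max=30,
        identity_threshold=0.85,
        seed=3,
    )
    return generate_template_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
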