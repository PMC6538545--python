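import numpy as np
import pytest

from simrepo.entities import AssociationSet
from simrepo.pipeline import compute_kernels
from simrepo.similarity import SimilarityMatrix
from simrepo.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """3-cluster, 3x3 zero-noise dataset: maximal within-cluster coherence.

    Three clusters keep the non-associated candidate space large enough for
    1:2 negative under-sampling.
    """
    return generate(
        SyntheticConfig(
            n_clusters=3, drugs_per_cluster=3, diseases_per_cluster=3,
            fingerprint_length=128, target_length=40, noise=0.0, seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_kernels(small_dataset):
    return compute_kernels(small_dataset)


@pytest.fixture(scope="session")
def study_dataset():
    """The reference study conditions: 4 clusters of 5x5 at noise 0.05."""
    return generate(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def study_kernels(study_dataset):
    return compute_kernels(study_dataset)


def random_kernel_set(rng, drug_ids, disease_ids, nan_rate=0.0):
    """Seven random valid similarity matrices over the given id lists."""

    def sym(ids):
        n = len(ids)
        v = rng.random((n, n))
        v = (v + v.T) / 2.0
        if nan_rate:
            mask = rng.random((n, n)) < nan_rate
            mask |= mask.T
            v[mask] = np.nan
        np.fill_diagonal(v, 1.0)
        return v

    mats = {}
    for kind in ("drChe", "drSE", "drGO", "drTar"):
        mats[kind] = SimilarityMatrix(kind, drug_ids, sym(drug_ids))
    for kind in ("diGO", "diHPO", "diPhe"):
        mats[kind] = SimilarityMatrix(kind, disease_ids, sym(disease_ids))
    return mats


def random_association_set(rng, drug_ids, disease_ids, n_pairs):
    all_pairs = [(d, s) for d in drug_ids for s in disease_ids]
    idx = rng.choice(len(all_pairs), size=min(n_pairs, len(all_pairs)), replace=False)
    return AssociationSet({all_pairs[i] for i in idx})
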