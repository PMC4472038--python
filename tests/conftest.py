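"""Shared fixtures: a synthetic atlas with held-out samples and one fitted
classifier, built once per session because the cross-validated path fit is
the expensive step."""

from __future__ import annotations

import pytest

import keygenes as kg

ATLAS_SEED = 0        # truth structure
COUNT_SEED = 1        # count draws
SPLIT_SEED = 2        # holdout split
FIT_SEED = 7          # CV folds


@pytest.fixture(scope="session")
def truth():
    return kg.SimulationTruth.default(seed=ATLAS_SEED)


@pytest.fixture(scope="session")
def atlas(truth):
    counts, labels = kg.simulate_tissue_counts(truth, samples_per_tissue=5,
                                               seed=COUNT_SEED)
    return counts, labels


@pytest.fixture(scope="session")
def split(atlas):
    counts, labels = atlas
    train_ids, test_ids = kg.holdout_split(labels, per_class=1, seed=SPLIT_SEED)
    return {
        "train": counts.select_samples(train_ids),
        "test": counts.select_samples(test_ids),
        "train_labels": labels.subset(train_ids),
        "test_labels": labels.subset(test_ids),
    }


@pytest.fixture(scope="session")
def train_cpm(split):
    return kg.cpm(split["train"])


@pytest.fixture(scope="session")
def top500(train_cpm):
    return kg.top_variable_genes(train_cpm, n=500)


@pytest.fixture(scope="session")
def fitted(split, train_cpm, top500):
    """Classifier fit on the training atlas against the held-out genes,
    with its identity scores and classifier genes."""
    model = kg.fit_classifier(
        train_cpm, split["train_labels"], top500,
        test_genes=split["test"].gene_ids, nfolds=10, seed=FIT_SEED,
    )
    scores = kg.predict_identity_scores(model, split["test"])
    genes = kg.extract_classifier_genes(model)
    return {"model": model, "scores": scores, "genes": genes}


@pytest.fixture(scope="session")
def small_truth():
    """A lighter atlas for end-to-end / CLI runs."""
    return kg.SimulationTruth.default(
        tissues=("brain", "heart", "liver", "kidney"),
        n_genes=800, markers_per_tissue=12, n_housekeepers=100,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_atlas(small_truth):
    return kg.simulate_tissue_counts(small_truth, samples_per_tissue=4, seed=6)
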