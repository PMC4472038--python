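"""Multinomial LASSO fitting, identity scores and classifier genes."""

import numpy as np
import pandas as pd
import pytest

import keygenes as kg
from oracles import l1_multinomial_reference


def _toy_problem(n_per_class=12, n_features=15, n_classes=3, sep=2.0, seed=0):
    """Standardized design with one informative feature per class."""
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    X = rng.normal(size=(n, n_features))
    y = np.repeat(np.arange(n_classes), n_per_class)
    for k in range(n_classes):
        X[y == k, k] += sep
    X = (X - X.mean(0)) / X.std(0)
    return X, y


def _toy_matrix(seed=0, n_classes=3):
    """Counts matrix + labels built from the toy design (via 2^x scaling)."""
    rng = np.random.default_rng(seed)
    X, y = _toy_problem(seed=seed, n_classes=n_classes)
    genes = [f"g{i}" for i in range(X.shape[1])]
    samples = [f"s{i}" for i in range(X.shape[0])]
    cpm_vals = np.round(2.0 ** (X.T + 8), 6)
    m = kg.ExpressionMatrix(pd.DataFrame(cpm_vals, index=genes, columns=samples), "cpm")
    labels = kg.LabelTable.from_mapping(
        {s: f"class{y[i]}" for i, s in enumerate(samples)}
    )
    return m, labels, genes


class TestComposeTrainingSet:
    def test_exclude_filters_classes(self, atlas):
        counts, labels = atlas
        m, lab = kg.compose_training_set(counts, labels,
                                         exclude={"skin", "muscle"})
        assert set(lab.classes()) == set(labels.classes()) - {"skin", "muscle"}
        assert m.n_samples == len(lab.sample_ids)

    def test_filter_removing_everything_errors(self, atlas):
        counts, labels = atlas
        with pytest.raises(ValueError, match="removed every"):
            kg.compose_training_set(counts, labels, include={"no_such_tissue"})

    def test_split_by_stage_doubles_classes(self, atlas):
        counts, labels = atlas
        m, lab = kg.compose_training_set(
            counts, labels, include={"brain", "liver"}, split_by_stage=True
        )
        assert set(lab.classes()) == {"brain_1T", "brain_2T", "liver_1T", "liver_2T"}

    def test_augment_intersects_genes(self, atlas, small_atlas):
        counts, labels = atlas
        extra_counts, extra_labels = small_atlas
        # rename the extra samples so IDs do not collide
        renamed = kg.ExpressionMatrix(
            extra_counts.data.rename(columns=lambda c: "x_" + c), "counts")
        relabeled = kg.LabelTable(
            extra_labels.table.rename(index=lambda c: "x_" + c))
        m, lab = kg.compose_training_set(
            counts, labels, augment=[(renamed, relabeled)])
        assert m.n_samples == counts.n_samples + renamed.n_samples
        assert set(m.gene_ids) <= set(counts.gene_ids) & set(renamed.gene_ids)

    def test_augment_with_disjoint_genes_errors(self, atlas):
        counts, labels = atlas
        other = kg.ExpressionMatrix(
            pd.DataFrame([[1, 2]], index=["ZZZ"], columns=["a1", "a2"]), "counts")
        other_labels = kg.LabelTable.from_mapping({"a1": "islet", "a2": "islet"})
        with pytest.raises(ValueError, match="no genes in common"):
            kg.compose_training_set(counts, labels, augment=[(other, other_labels)])


class TestFitClassifier:
    def test_coefficients_match_generic_convex_solver(self):
        """At fixed penalties the coefficients agree with an independent
        optimizer of the same L1-penalized multinomial objective."""
        X, y = _toy_problem()
        m, labels, genes = _toy_matrix()
        for lam in (0.02, 0.06):
            model = kg.fit_classifier(
                m, labels, genes, fixed_penalty=lam,
                tol=1e-12, max_iter=500_000,
            )
            ref_coef, ref_icpt, ref_classes = l1_multinomial_reference(
                _standardized(m, genes, model), _labels_as_int(labels, m), lam
            )
            np.testing.assert_allclose(model.coefficients, ref_coef, atol=1e-6)
            np.testing.assert_allclose(model.intercepts, ref_icpt, atol=1e-6)

    def test_max_penalty_gives_intercept_only_model(self):
        m, labels, genes = _toy_matrix()
        model = kg.fit_classifier(m, labels, genes, fixed_penalty=10.0)
        assert np.all(model.coefficients == 0.0)
        scores = kg.predict_identity_scores(model, m)
        expected = model.class_priors[:, None] * np.ones((1, m.n_samples))
        np.testing.assert_allclose(scores.scores.to_numpy(), expected, atol=1e-12)

    def test_two_class_separating_gene_dominates(self):
        """With one perfectly separating gene the fit concentrates weight on
        it, and probabilities match the independent solver."""
        rng = np.random.default_rng(4)
        n = 24
        X = rng.normal(0, 0.3, size=(n, 8))
        y = np.repeat([0, 1], n // 2)
        X[:, 5] = np.where(y == 0, -1.0, 1.0) + rng.normal(0, 0.05, n)
        X = (X - X.mean(0)) / X.std(0)
        genes = [f"g{i}" for i in range(8)]
        samples = [f"s{i}" for i in range(n)]
        m = kg.ExpressionMatrix(
            pd.DataFrame(np.round(2.0 ** (X.T + 8), 6), index=genes, columns=samples),
            "cpm")
        labels = kg.LabelTable.from_mapping({s: f"c{y[i]}" for i, s in enumerate(samples)})
        lam = 0.05
        model = kg.fit_classifier(m, labels, genes, fixed_penalty=lam,
                                  tol=1e-12, max_iter=500_000)
        mags = np.abs(model.coefficients).max(axis=0)
        assert np.argmax(mags) == 5
        # two-class coefficients are only identified through their difference
        ref_coef, ref_icpt, _ = l1_multinomial_reference(
            _standardized(m, genes, model), _labels_as_int(labels, m), lam)
        diff = model.coefficients[1] - model.coefficients[0]
        np.testing.assert_allclose(diff, ref_coef[0], atol=1e-6)

    def test_seed_changes_folds_not_holdout_calls(self, split, train_cpm, top500, fitted):
        model_b = kg.fit_classifier(
            train_cpm, split["train_labels"], top500,
            test_genes=split["test"].gene_ids, nfolds=10, seed=FIT_SEED_ALT,
            cv_max_iter=150, max_iter=1000,
        )
        calls_a = kg.predict_identity_scores(fitted["model"], split["test"]).best_hits()
        calls_b = kg.predict_identity_scores(model_b, split["test"]).best_hits()
        assert (calls_a == calls_b).all()

    def test_determinism_same_seed_identical(self):
        m, labels, genes = _toy_matrix()
        a = kg.fit_classifier(m, labels, genes, nfolds=4, seed=3)
        b = kg.fit_classifier(m, labels, genes, nfolds=4, seed=3)
        assert a.selected_penalty == b.selected_penalty
        np.testing.assert_array_equal(a.coefficients, b.coefficients)
        np.testing.assert_array_equal(a.path_coefficients, b.path_coefficients)

    def test_sparsity_grows_as_penalty_shrinks(self, fitted):
        """The active set is empty at the maximal penalty and grows along
        the path; individual coordinates may transiently drop out (L1 paths
        are not strictly monotone), but never more than a few at a time."""
        nnz = fitted["model"].n_nonzero_path()
        assert nnz[0] == 0
        # local dips stay small relative to the active set (~160 genes here)
        assert np.all(np.diff(nnz) >= -10)
        assert nnz[-1] == nnz.max()

    def test_single_class_rejected(self):
        m, labels, genes = _toy_matrix()
        one = kg.LabelTable.from_mapping({s: "same" for s in m.sample_ids})
        with pytest.raises(ValueError, match="two classes"):
            kg.fit_classifier(m, one, genes)

    def test_empty_feature_space_rejected(self, train_cpm, split, top500):
        with pytest.raises(ValueError, match="empty feature space"):
            kg.fit_classifier(train_cpm, split["train_labels"], top500,
                              test_genes=["NOPE"])


class TestPredict:
    def test_columns_sum_to_one(self, fitted):
        sums = fitted["scores"].scores.sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_missing_feature_gene_named(self, fitted, split):
        test = split["test"]
        dropped = test.select_genes(
            [g for g in test.gene_ids if g != fitted["model"].feature_genes[0]])
        with pytest.raises(ValueError, match=fitted["model"].feature_genes[0]):
            kg.predict_identity_scores(fitted["model"], dropped)

    def test_intensity_input_rejected_without_scaling(self, fitted, split):
        test = split["test"]
        inten = kg.ExpressionMatrix(test.data.astype(float), "intensity")
        with pytest.raises(ValueError, match="scaled onto the training"):
            kg.predict_identity_scores(fitted["model"], inten)

    def test_best_hit_geq_second_hit(self, fitted):
        calls = fitted["scores"].calls()
        assert (calls["best_score"] >= calls["second_score"]).all()


class TestClassifierGenes:
    def test_intercept_only_model_has_empty_sets(self):
        m, labels, genes = _toy_matrix()
        model = kg.fit_classifier(m, labels, genes, fixed_penalty=10.0)
        out = kg.extract_classifier_genes(model)
        assert out.n_genes() == 0
        assert all(len(v) == 0 for v in out.per_class.values())

    def test_extraction_deterministic(self, fitted):
        a = kg.extract_classifier_genes(fitted["model"])
        b = kg.extract_classifier_genes(fitted["model"])
        assert a.per_class == b.per_class

    def test_genes_sorted_by_magnitude_and_nonzero(self, fitted):
        out = fitted["genes"]
        for cls, genes in out.per_class.items():
            mags = [abs(c) for _, c in genes]
            assert all(m > 0 for m in mags)
            assert mags == sorted(mags, reverse=True)

    def test_multi_class_membership_reported(self, fitted):
        membership = fitted["genes"].gene_classes()
        assert fitted["genes"].n_genes() == len(membership)
        assert all(len(v) >= 1 for v in membership.values())

    def test_intersection_across_runs(self, fitted):
        inter = fitted["genes"].intersect(fitted["genes"])
        assert inter == fitted["genes"].union()


FIT_SEED_ALT = 99


def _standardized(m, genes, model):
    X = np.log2(m.select_genes(list(genes)).values + 1.0).T
    return (X - model.transform_means) / model.transform_scales


def _labels_as_int(labels, m):
    classes = sorted(set(labels.table["class_label"]))
    return np.array([classes.index(labels.class_of(s)) for s in m.sample_ids])
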