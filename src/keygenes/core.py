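"""Identity scoring by cross-validated multinomial LASSO.

A multinomial logistic model with an L1 penalty is fit to the training
atlas, restricted to the candidate feature pool (the most variable training
genes) intersected with the genes measured in the test set.  The penalty is
chosen by seeded stratified k-fold cross-validation on multinomial deviance.
Per-sample identity scores are the fitted class probabilities (softmax of
the per-class linear predictors), so every score column lies in [0, 1] and
sums to one.  The genes with nonzero coefficients at the selected penalty
are the classifier genes — the transcriptional barcode of the classes.

Inputs are transformed to log2(CPM+1) and standardized per gene; the
standardization means and scales are estimated on the training set only and
reused verbatim for test samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._lasso import fit_multinomial_lasso_path
from .expression import ExpressionMatrix, LabelTable, align_genes
from .feature_selection import VariableGeneList
from .normalization import cpm

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-10  # deviance clip for classes absent from a CV training fold


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """Fitted multinomial LASSO state.

    ``coefficients`` (classes x features) and ``intercepts`` are on the
    standardized log2(CPM+1) scale at ``selected_penalty``.  The full-data
    coefficient path is retained so the sparsity trajectory can be
    inspected and penalties forced after the fact.
    """

    classes: list
    feature_genes: list
    coefficients: np.ndarray
    intercepts: np.ndarray
    penalty_path: np.ndarray
    selected_penalty: float
    selection_rule: str
    transform_means: np.ndarray
    transform_scales: np.ndarray
    class_priors: np.ndarray
    fold_seed: int
    nfolds: int
    path_coefficients: np.ndarray  # (n_penalties, n_classes, n_features)
    path_intercepts: np.ndarray    # (n_penalties, n_classes)
    cv_mean_deviance: Optional[np.ndarray] = None
    cv_se_deviance: Optional[np.ndarray] = None
    fold_ids: Optional[np.ndarray] = None
    input_transform: str = "standardized log2(CPM+1)"

    def __post_init__(self) -> None:
        k, p = len(self.classes), len(self.feature_genes)
        if self.coefficients.shape != (k, p):
            raise ValueError("coefficient matrix shape mismatch")
        if not np.any(np.isclose(self.selected_penalty, self.penalty_path)):
            raise ValueError("selected penalty not on the penalty path")

    def coefficients_at(self, penalty: float) -> Tuple[np.ndarray, np.ndarray]:
        """Path coefficients and intercepts at the path value nearest ``penalty``."""
        idx = int(np.argmin(np.abs(np.log(self.penalty_path) - np.log(penalty))))
        return self.path_coefficients[idx], self.path_intercepts[idx]

    def n_nonzero_path(self) -> np.ndarray:
        """Number of features with any nonzero class coefficient, per penalty."""
        return np.count_nonzero(np.any(self.path_coefficients != 0, axis=1), axis=1)


@dataclass
class IdentityScoreMatrix:
    """Class-by-sample identity scores with best/second-best calls."""

    scores: pd.DataFrame  # classes x samples

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if vals.size == 0:
            raise ValueError("empty score matrix")
        if np.min(vals) < -1e-12 or np.max(vals) > 1 + 1e-12:
            raise ValueError("identity scores must lie in [0, 1]")
        sums = vals.sum(axis=0)
        if np.max(np.abs(sums - 1.0)) > 1e-8:
            bad = self.scores.columns[int(np.argmax(np.abs(sums - 1.0)))]
            raise ValueError(f"score column for sample {bad!r} does not sum to 1")

    @property
    def classes(self) -> list:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list:
        return list(self.scores.columns)

    def calls(self) -> pd.DataFrame:
        """Best and second-best class per sample."""
        rows = []
        for sample in self.scores.columns:
            col = self.scores[sample].sort_values(ascending=False, kind="stable")
            rows.append(
                {
                    "sample_id": sample,
                    "best_class": col.index[0],
                    "best_score": col.iloc[0],
                    "second_class": col.index[1] if len(col) > 1 else "",
                    "second_score": col.iloc[1] if len(col) > 1 else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("sample_id")

    def best_hits(self) -> pd.Series:
        return self.calls()["best_class"]


@dataclass
class ClassifierGeneSet:
    """Per-class classifier genes (nonzero LASSO coefficients).

    ``per_class`` maps class -> list of (gene, coefficient) sorted by
    descending |coefficient|.  A gene may serve several classes.
    """

    per_class: dict
    selected_penalty: float

    def union(self) -> set:
        return {g for genes in self.per_class.values() for g, _ in genes}

    def gene_classes(self) -> dict:
        """Deduplicated union with per-gene class membership."""
        out: dict = {}
        for cls, genes in self.per_class.items():
            for g, _ in genes:
                out.setdefault(g, []).append(cls)
        return out

    def n_genes(self) -> int:
        return len(self.union())

    def table(self) -> pd.DataFrame:
        rows = [
            {"class": cls, "gene": g, "coefficient": c}
            for cls, genes in self.per_class.items()
            for g, c in genes
        ]
        return pd.DataFrame(rows, columns=["class", "gene", "coefficient"])

    def intersect(self, *others: "ClassifierGeneSet") -> set:
        """Genes common to this and all other runs' unions."""
        common = self.union()
        for o in others:
            common &= o.union()
        return common


# ---------------------------------------------------------------------------
# training-set composition
# ---------------------------------------------------------------------------

def compose_training_set(
    m: ExpressionMatrix,
    labels: LabelTable,
    include: Optional[Iterable[str]] = None,
    exclude: Optional[Iterable[str]] = None,
    split_by_stage: bool = False,
    augment: Optional[Sequence[Tuple[ExpressionMatrix, LabelTable]]] = None,
) -> Tuple[ExpressionMatrix, LabelTable]:
    """Assemble a (possibly filtered, stage-split, augmented) training set.

    ``include``/``exclude`` filter tissue classes; ``split_by_stage``
    renames classes to ``class_stage`` (e.g. ``pancreas_1T``) for samples
    carrying a stage annotation; ``augment`` merges further labelled
    datasets on the gene-namespace intersection.
    """
    labelled = [s for s in m.sample_ids if s in labels.table.index]
    m = m.select_samples(labelled)
    lab = labels.subset(labelled).table.copy()

    if include is not None:
        include = set(include)
        keep = lab.index[lab["class_label"].isin(include)]
        if len(keep) == 0:
            raise ValueError("class filter removed every training sample")
        m, lab = m.select_samples(list(keep)), lab.loc[keep]
    if exclude is not None:
        exclude = set(exclude)
        keep = lab.index[~lab["class_label"].isin(exclude)]
        if len(keep) == 0:
            raise ValueError("class filter removed every training sample")
        m, lab = m.select_samples(list(keep)), lab.loc[keep]

    matrices = [m]
    tables = [lab]
    if augment:
        for extra_m, extra_l in augment:
            ids = [s for s in extra_m.sample_ids if s in extra_l.table.index]
            matrices.append(extra_m.select_samples(ids))
            tables.append(extra_l.subset(ids).table.copy())

    # intersect gene namespaces pairwise, preserving the base order
    base = matrices[0]
    for other in matrices[1:]:
        base, _ = align_genes(base, other)
    genes = base.gene_ids
    matrices = [mx.select_genes(genes) for mx in matrices]

    all_samples: list = []
    for mx in matrices:
        for s in mx.sample_ids:
            if s in all_samples:
                raise ValueError(f"duplicate sample ID across training sets: {s!r}")
            all_samples.append(s)

    merged = pd.concat([mx.data for mx in matrices], axis=1)
    merged_labels = pd.concat(tables, axis=0)
    if split_by_stage:
        staged = merged_labels["stage"].notna() & (merged_labels["stage"].astype(str) != "")
        merged_labels.loc[staged, "class_label"] = (
            merged_labels.loc[staged, "class_label"]
            + "_"
            + merged_labels.loc[staged, "stage"].astype(str)
        )
    platform = matrices[0].platform
    return (
        ExpressionMatrix(merged, platform, dict(m.meta)),
        LabelTable(merged_labels),
    )


def holdout_split(
    labels: LabelTable, per_class: int = 1, seed: int = 0
) -> Tuple[list, list]:
    """Seeded split holding out ``per_class`` samples from every class."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in labels.classes():
        ids = [s for s in labels.sample_ids if labels.class_of(s) == cls]
        ids = list(rng.permutation(ids))
        test.extend(ids[:per_class])
        train.extend(ids[per_class:])
    return sorted(train), sorted(test)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _to_logcpm(m: ExpressionMatrix) -> ExpressionMatrix:
    if m.platform == "counts":
        m = cpm(m)
    elif m.platform == "intensity":
        raise ValueError(
            "intensity data must be scaled onto the training CPM scale first "
            "(see keygenes.platform_bridge)"
        )
    return m


def _assign_folds(y: np.ndarray, n_classes: int, nfolds: int, seed: int) -> np.ndarray:
    """Stratified seeded fold assignment (per-class round robin).

    Classes with fewer samples than folds are spread over a random subset of
    folds, so single-sample classes join the partition unstratified.
    """
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for k in range(n_classes):
        idx = np.nonzero(y == k)[0]
        idx = rng.permutation(idx)
        start = int(rng.integers(nfolds))
        folds[idx] = (start + np.arange(len(idx))) % nfolds
    return folds


def _lambda_path(
    X: np.ndarray, y: np.ndarray, n_classes: int,
    n_penalties: int, min_ratio: Optional[float],
) -> np.ndarray:
    n = len(y)
    priors = np.bincount(y, minlength=n_classes) / n
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    grad0 = X.T @ (onehot - priors) / n  # (P, K) score at the null model
    lam_max = float(np.max(np.abs(grad0)))
    if lam_max <= 0:
        lam_max = 1e-3
    if min_ratio is None:
        min_ratio = 1e-4
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_penalties)


def _fit_path(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    lambdas: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 20000,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Warm-started L1 multinomial fits along a decreasing penalty path.

    Returns (coefs, intercepts, classes_present): coefs has shape
    (L, n_classes, P) with zero rows for classes absent from ``y``.
    """
    return fit_multinomial_lasso_path(X, y, n_classes, lambdas, tol, max_iter)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _path_probabilities(
    coefs: np.ndarray, icpts: np.ndarray, present: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """(L, n, K) class probabilities; classes absent from training get 0."""
    L, K, _ = coefs.shape
    out = np.zeros((L, X.shape[0], K))
    for li in range(L):
        z = X @ coefs[li].T + icpts[li]
        if len(present) < K:
            probs = np.zeros_like(z)
            probs[:, present] = _softmax(z[:, present])
        else:
            probs = _softmax(z)
        out[li] = probs
    return out


def fit_classifier(
    train: ExpressionMatrix,
    labels: LabelTable,
    candidate_genes: VariableGeneList | Sequence[str],
    test_genes: Optional[Sequence[str]] = None,
    nfolds: int = 10,
    rule: str = "min",
    seed: int = 0,
    n_penalties: int = 100,
    penalty_min_ratio: Optional[float] = None,
    penalty_path: Optional[Sequence[float]] = None,
    fixed_penalty: Optional[float] = None,
    tol: float = 1e-6,
    max_iter: int = 3000,
    cv_tol: float = 1e-4,
    cv_max_iter: int = 300,
) -> TrainedClassifier:
    """Fit the multinomial LASSO and select its penalty by cross-validation.

    The feature space is ``candidate_genes`` intersected with the genes of
    the test set (when given) and of the training matrix — the model is
    refit per query so that only genes actually measured in the query can
    carry weight.  With ``fixed_penalty`` the cross-validation is skipped
    and the model is reported at that penalty.
    """
    if rule not in ("min", "one_se"):
        raise ValueError("rule must be 'min' or 'one_se'")
    train_cpm = _to_logcpm(train)
    gene_pool = list(candidate_genes.gene_ids if isinstance(candidate_genes, VariableGeneList)
                     else candidate_genes)
    train_set = set(train_cpm.gene_ids)
    test_set = set(test_genes) if test_genes is not None else None
    features = [
        g for g in gene_pool
        if g in train_set and (test_set is None or g in test_set)
    ]
    if not features:
        raise ValueError("empty feature space: no candidate gene is shared "
                         "by training and test sets")

    y_labels = labels.labels_for(train_cpm.sample_ids)
    classes = sorted(y_labels.unique())
    if len(classes) < 2:
        raise ValueError("training set must contain at least two classes")
    labels.warn_small_classes()
    y = np.array([classes.index(c) for c in y_labels])
    n, k = len(y), len(classes)

    X_raw = np.log2(train_cpm.select_genes(features).values + 1.0).T  # n x P
    means = X_raw.mean(axis=0)
    scales = X_raw.std(axis=0)
    scales[scales == 0] = 1.0
    X = (X_raw - means) / scales

    if penalty_path is not None:
        path = np.sort(np.asarray(penalty_path, dtype=float))[::-1]
    else:
        path = _lambda_path(X, y, k, n_penalties, penalty_min_ratio)
    if fixed_penalty is not None:
        path = np.array(sorted(set(path[path > fixed_penalty]) | {float(fixed_penalty)},
                               reverse=True))

    cv_mean = cv_se = fold_ids = None
    if fixed_penalty is not None:
        selected = float(fixed_penalty)
    elif len(path) == 1:
        selected = float(path[0])
    else:
        if nfolds > n:
            logger.warning("nfolds=%d exceeds n=%d samples; reducing", nfolds, n)
            nfolds = n
        if nfolds < 2:
            raise ValueError("need at least 2 cross-validation folds")
        fold_ids = _assign_folds(y, k, nfolds, seed)
        fold_dev = np.full((nfolds, len(path)), np.nan)
        for f in range(nfolds):
            tr = fold_ids != f
            te = ~tr
            if len(np.unique(y[tr])) < 2 or not te.any():
                continue
            coefs, icpts, present = _fit_path(X[tr], y[tr], k, path, cv_tol, cv_max_iter)
            probs = _path_probabilities(coefs, icpts, present, X[te])
            p_true = np.clip(probs[:, np.arange(te.sum()), y[te]], _PROB_FLOOR, 1.0)
            fold_dev[f] = -2.0 * np.log(p_true).mean(axis=1)
        ok = ~np.isnan(fold_dev).any(axis=1)
        if not ok.any():
            raise ValueError("no usable cross-validation folds")
        cv_mean = fold_dev[ok].mean(axis=0)
        cv_se = fold_dev[ok].std(axis=0, ddof=1) / np.sqrt(ok.sum())
        i_min = int(np.argmin(cv_mean))
        if rule == "min":
            selected = float(path[i_min])
        else:
            within = np.nonzero(cv_mean <= cv_mean[i_min] + cv_se[i_min])[0]
            selected = float(path[within.min()])  # path is decreasing

    coefs, icpts, present = _fit_path(X, y, k, path, tol, max_iter)
    sel_idx = int(np.argmin(np.abs(path - selected)))
    priors = np.bincount(y, minlength=k) / n

    logger.info(
        "fit_classifier: %d classes, %d features, selected penalty %.5g "
        "(%s rule), %d classifier genes",
        k, len(features), selected, rule,
        int(np.count_nonzero(np.any(coefs[sel_idx] != 0, axis=0))),
    )
    return TrainedClassifier(
        classes=classes,
        feature_genes=features,
        coefficients=coefs[sel_idx],
        intercepts=icpts[sel_idx],
        penalty_path=path,
        selected_penalty=selected,
        selection_rule=rule if fixed_penalty is None else "fixed",
        transform_means=means,
        transform_scales=scales,
        class_priors=priors,
        fold_seed=seed,
        nfolds=nfolds,
        path_coefficients=coefs,
        path_intercepts=icpts,
        cv_mean_deviance=cv_mean,
        cv_se_deviance=cv_se,
        fold_ids=fold_ids,
    )


def predict_identity_scores(
    model: TrainedClassifier, test: ExpressionMatrix
) -> IdentityScoreMatrix:
    """Identity scores (class probabilities) for each test sample.

    Test counts are converted to CPM with their own TMM factors, log2(x+1)
    transformed, and standardized with the training means and scales stored
    on the model.
    """
    test_cpm = _to_logcpm(test)
    missing = [g for g in model.feature_genes if g not in set(test_cpm.gene_ids)]
    if missing:
        raise ValueError(f"test set lacks feature genes: {missing[:5]}")
    X_raw = np.log2(test_cpm.select_genes(model.feature_genes).values + 1.0).T
    X = (X_raw - model.transform_means) / model.transform_scales
    z = X @ model.coefficients.T + model.intercepts
    probs = _softmax(z)
    scores = pd.DataFrame(
        probs.T, index=pd.Index(model.classes, name="class"),
        columns=test_cpm.sample_ids,
    )
    return IdentityScoreMatrix(scores)


def extract_classifier_genes(
    model: TrainedClassifier, penalty: Optional[float] = None
) -> ClassifierGeneSet:
    """Genes with nonzero coefficients at the selected (or given) penalty."""
    if penalty is None:
        coefs = model.coefficients
        penalty = model.selected_penalty
    else:
        coefs, _ = model.coefficients_at(penalty)
    per_class = {}
    for ki, cls in enumerate(model.classes):
        nz = np.nonzero(coefs[ki])[0]
        genes = sorted(
            ((model.feature_genes[j], float(coefs[ki, j])) for j in nz),
            key=lambda gc: (-abs(gc[1]), gc[0]),
        )
        per_class[cls] = genes
    return ClassifierGeneSet(per_class=per_class, selected_penalty=float(penalty))
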