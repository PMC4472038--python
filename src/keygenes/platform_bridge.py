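"""Scaling microarray intensities onto the NGS training scale.

Microarray fluorescence and NGS counts live on different scales, so before
a microarray test set can be scored against an NGS training atlas each
array sample is mapped onto the training CPM scale.  The anchors are
housekeeping genes — genes expressed stably across tissues — present in
both datasets and detectably expressed in the training set.  Three
reconstructions of the mapping are provided:

``affine``
    per-sample robust straight line in log space, fit by least absolute
    deviations (median regression) from the sample's housekeeping
    log-intensities to the training-mean housekeeping log-CPM profile,
    then applied to every gene of the sample;
``offset``
    gain fixed to 1; the offset is the median housekeeping log-ratio;
``quantile``
    monotone map sending the sample's housekeeping intensity quantiles
    onto the training housekeeping log-CPM quantiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .expression import ExpressionMatrix, GenePanel
from .normalization import cpm

logger = logging.getLogger(__name__)

SCALING_MODES = ("affine", "offset", "quantile")
MIN_HOUSEKEEPERS = 10


@dataclass
class HousekeeperScaling:
    """Housekeeping anchor genes plus fitted per-sample map parameters."""

    housekeepers_used: list
    panel_name: str = "housekeepers"
    mode: str = "affine"
    # per test sample: {"offset": a, "gain": b, "median_abs_residual": r}
    sample_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.housekeepers_used:
            raise ValueError("no usable housekeeping genes")


def _as_cpm(train: ExpressionMatrix) -> ExpressionMatrix:
    return cpm(train) if train.platform == "counts" else train


def select_housekeepers(
    panel: GenePanel,
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    detection_cpm: float = 1.0,
) -> HousekeeperScaling:
    """Panel genes present in both datasets and expressed in training.

    "Expressed" means CPM at or above ``detection_cpm`` in at least one
    training sample.
    """
    train_cpm = _as_cpm(train)
    train_genes = set(train_cpm.gene_ids)
    test_genes = set(test.gene_ids)
    shared = [g for g in panel.gene_ids if g in train_genes and g in test_genes]
    if not shared:
        raise ValueError(
            "no housekeeping panel gene is shared by training and test sets; "
            "check the gene identifier namespace"
        )
    expressed_mask = (train_cpm.select_genes(shared).data >= detection_cpm).any(axis=1)
    used = [g for g in shared if expressed_mask[g]]
    if not used:
        raise ValueError(
            "no shared housekeeping gene is expressed in the training set "
            f"(CPM >= {detection_cpm} in >= 1 sample)"
        )
    logger.info(
        "select_housekeepers: %d of %d panel genes usable (%d shared)",
        len(used), len(panel), len(shared),
    )
    return HousekeeperScaling(housekeepers_used=used, panel_name=panel.name)


def _lad_affine(x: np.ndarray, y: np.ndarray) -> tuple:
    """Least-absolute-deviations line y ~ a + b*x, solved exactly as an LP."""
    m = len(x)
    # variables: a, b, u_1..u_m ; minimize sum u, |a + b x - y| <= u
    c = np.concatenate([[0.0, 0.0], np.ones(m)])
    eye = np.eye(m)
    a_ub = np.vstack(
        [
            np.column_stack([np.ones(m), x, -eye]),
            np.column_stack([-np.ones(m), -x, -eye]),
        ]
    )
    b_ub = np.concatenate([y, -y])
    res = linprog(
        c, A_ub=a_ub, b_ub=b_ub,
        bounds=[(None, None), (None, None)] + [(0, None)] * m,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"LAD fit failed: {res.message}")
    return float(res.x[0]), float(res.x[1])


def scale_to_training(
    test: ExpressionMatrix,
    train: ExpressionMatrix,
    hk: HousekeeperScaling,
    mode: str = "affine",
) -> ExpressionMatrix:
    """Map each test sample onto the training CPM scale via its housekeepers.

    All arithmetic happens on log2(x+1); the mapped values are
    exponentiated back and clipped at zero, and the result is tagged as
    CPM-comparable so it can feed ``predict_identity_scores`` directly.
    """
    if mode not in SCALING_MODES:
        raise ValueError(f"unknown scaling mode {mode!r}; expected one of {SCALING_MODES}")
    usable = [g for g in hk.housekeepers_used if g in set(test.gene_ids)]
    if len(usable) < MIN_HOUSEKEEPERS:
        raise ValueError(
            f"only {len(usable)} usable housekeeping genes; "
            f">= {MIN_HOUSEKEEPERS} needed for a stable fit"
        )
    train_cpm = _as_cpm(train)
    target = np.log2(train_cpm.select_genes(usable).values + 1.0).mean(axis=1)

    log_test = np.log2(test.values + 1.0)
    hk_idx = [test.gene_ids.index(g) for g in usable]
    out = np.empty_like(log_test)
    params = {}
    for si, sample in enumerate(test.sample_ids):
        x = log_test[hk_idx, si]
        if mode == "affine":
            a, b = _lad_affine(x, target)
            mapped = a + b * log_test[:, si]
            resid = np.abs(a + b * x - target)
        elif mode == "offset":
            a = float(np.median(target - x))
            b = 1.0
            mapped = a + log_test[:, si]
            resid = np.abs(a + x - target)
        else:  # quantile
            order = np.argsort(x, kind="stable")
            xs = x[order]
            ys = np.sort(target)
            mapped = np.interp(log_test[:, si], xs, ys)
            a, b = float(np.median(ys - xs)), 1.0
            resid = np.abs(np.interp(x, xs, ys) - target)
        out[:, si] = mapped
        params[sample] = {
            "offset": a,
            "gain": b,
            "median_abs_residual": float(np.median(resid)),
        }
        logger.info(
            "scale_to_training[%s]: %s offset=%.4f gain=%.4f median|resid|=%.4f",
            sample, mode, a, b, params[sample]["median_abs_residual"],
        )
    hk.mode = mode
    hk.sample_params = params
    values = np.clip(2.0 ** out - 1.0, 0.0, None)
    meta = dict(test.meta)
    meta["scaling"] = f"housekeeper {mode} ({len(usable)} genes, panel {hk.panel_name})"
    return ExpressionMatrix(
        pd.DataFrame(values, index=test.data.index, columns=test.data.columns),
        "cpm",
        meta,
    )
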