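"""Selection of the most variably expressed genes across a dataset.

The candidate feature pool of the classifier is the top N (default 500)
genes ranked by expression variance across all samples of the training
dataset.  Variance is computed on log2(CPM+1) by default — the log transform
keeps a handful of extremely abundant genes from dominating the ranking —
with plain CPM variance available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix
from .normalization import cpm

logger = logging.getLogger(__name__)

MEASURES = ("variance_logcpm", "variance_cpm")


@dataclass
class VariableGeneList:
    """Genes ranked by descending expression variability."""

    gene_ids: list
    scores: np.ndarray
    n_requested: int
    source_dataset: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)


def top_variable_genes(
    m: ExpressionMatrix,
    n: int = 500,
    measure: str = "variance_logcpm",
) -> VariableGeneList:
    """Rank genes by expression variance and return the top ``n``.

    Accepts a CPM matrix or raw counts (CPM with TMM factors is then
    computed internally).  Ties are broken by gene ID so the ranking is
    deterministic; if fewer than ``n`` genes are available, all are
    returned with a warning.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if m.platform == "counts":
        m = cpm(m)
    elif m.platform != "cpm":
        raise ValueError("top_variable_genes expects counts or CPM input")

    values = m.values
    if measure == "variance_logcpm":
        values = np.log2(values + 1.0)
    scores = values.var(axis=1, ddof=1) if m.n_samples > 1 else np.zeros(m.n_genes)

    order = sorted(range(m.n_genes), key=lambda i: (-scores[i], m.gene_ids[i]))
    if n > m.n_genes:
        logger.warning(
            "requested top %d genes but only %d available; returning all", n, m.n_genes
        )
    top = order[: min(n, m.n_genes)]
    return VariableGeneList(
        gene_ids=[m.gene_ids[i] for i in top],
        scores=scores[top],
        n_requested=n,
        source_dataset=m.meta.get("source", ""),
    )
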