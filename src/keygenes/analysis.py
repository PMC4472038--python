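"""Supporting analyses: barcode bins, clustering, within-group correlation,
and stage-specific gene partitions.

These operate on CPM matrices and a label table and reproduce the standard
descriptive views of a tissue barcode: expression-level bins per
(gene, class), complete-linkage hierarchical clustering on 1 - Pearson
correlation, mean within-class correlation, and per-organ sets of genes
that are "high" (>10x the dataset mean) in one or more stage datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix, LabelTable

logger = logging.getLogger(__name__)

# CPM bin edges of the barcode heatmap; boundary values go to the lower-named
# bin, so the intervals are [0,50), [50,100], (100,1000], (1000,inf).
BIN_LABELS = ("<50", "50-100", "100-1000", ">1000")


def _bin_of(value: float) -> str:
    if value < 50:
        return "<50"
    if value <= 100:
        return "50-100"
    if value <= 1000:
        return "100-1000"
    return ">1000"


def barcode_bins(
    cpm: ExpressionMatrix,
    labels: LabelTable,
    genes: Sequence[str],
    classifier_classes: Optional[Dict[str, List[str]]] = None,
    by_stage: bool = False,
) -> pd.DataFrame:
    """Mean CPM per (gene, class[, stage]) assigned to barcode bins.

    ``classifier_classes`` (gene -> classes it classifies) fills the
    ``in_classifying_tissue`` flag that separates the green from the blue
    half of the barcode heatmap.
    """
    if cpm.platform != "cpm":
        raise ValueError("barcode_bins expects a CPM matrix")
    sub = cpm.select_genes(list(genes))
    lab = labels.table.loc[[s for s in sub.sample_ids if s in labels.table.index]]
    group_cols = ["class_label", "stage"] if by_stage else ["class_label"]
    rows = []
    for key, members in lab.groupby(group_cols, dropna=False, sort=True):
        if not by_stage:
            key = (key[0] if isinstance(key, tuple) else key, None)
        cls, stage = key
        means = sub.data[list(members.index)].mean(axis=1)
        for g in genes:
            in_classifying = (
                cls in classifier_classes.get(g, []) if classifier_classes else False
            )
            rows.append(
                {
                    "gene": g,
                    "class": cls,
                    "stage": stage,
                    "mean_cpm": float(means[g]),
                    "bin": _bin_of(float(means[g])),
                    "in_classifying_tissue": in_classifying,
                }
            )
    return pd.DataFrame(rows)


def pearson_distance_matrix(
    cpm: ExpressionMatrix, genes: Sequence[str]
) -> pd.DataFrame:
    """1 - Pearson correlation between sample CPM vectors over ``genes``."""
    sub = cpm.select_genes(list(genes)).values
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        bad = cpm.sample_ids[int(np.argmax(sd == 0))]
        raise ValueError(
            f"sample {bad!r} has zero variance over the gene list; "
            "Pearson correlation undefined"
        )
    corr = np.corrcoef(sub.T)
    return pd.DataFrame(1.0 - corr, index=cpm.sample_ids, columns=cpm.sample_ids)


@dataclass
class Dendrogram:
    """Complete-linkage clustering result (scipy linkage encoding)."""

    linkage_matrix: np.ndarray
    sample_ids: list

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        n = len(self.sample_ids)
        names = {i: self.sample_ids[i] for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for mi, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = heights[a]
            lb = heights[b]
            node = n + mi
            names[node] = (
                f"({names[a]}:{h - la:.6g},{names[b]}:{h - lb:.6g})"
            )
            heights[node] = h
        return names[n + len(self.linkage_matrix) - 1] + ";"


def cluster_samples(cpm: ExpressionMatrix, genes: Sequence[str]) -> Dendrogram:
    """Complete-linkage agglomeration on 1 - Pearson correlation distances."""
    if cpm.n_samples < 2:
        raise ValueError("clustering needs at least two samples")
    dist = pearson_distance_matrix(cpm, genes)
    condensed = squareform(dist.to_numpy(), checks=False)
    z = linkage(condensed, method="complete")
    return Dendrogram(linkage_matrix=z, sample_ids=cpm.sample_ids)


def mean_group_correlation(
    cpm: ExpressionMatrix,
    labels: LabelTable,
    genes: Sequence[str],
    grouping: str = "by_class",
) -> pd.DataFrame:
    """Mean +/- SD of within-group pairwise Pearson correlation.

    Groups are tissue classes (``by_class``) or class/stage combinations
    (``by_class_and_stage``); single-sample groups are skipped with a
    warning.  The last row, ``__overall__``, averages the group means.
    """
    if grouping not in ("by_class", "by_class_and_stage"):
        raise ValueError("grouping must be 'by_class' or 'by_class_and_stage'")
    sub = cpm.select_genes(list(genes))
    lab = labels.table.loc[[s for s in sub.sample_ids if s in labels.table.index]].copy()
    if grouping == "by_class_and_stage":
        staged = lab["stage"].notna()
        lab["group"] = lab["class_label"].where(
            ~staged, lab["class_label"] + "_" + lab["stage"].astype(str)
        )
    else:
        lab["group"] = lab["class_label"]

    rows = []
    group_means = []
    for group, members in lab.groupby("group", sort=True):
        ids = list(members.index)
        if len(ids) < 2:
            logger.warning("group %r has a single sample; skipped", group)
            continue
        vals = sub.data[ids].to_numpy()
        corr = np.corrcoef(vals.T)
        pairs = corr[np.triu_indices(len(ids), k=1)]
        rows.append(
            {
                "group": group,
                "n_samples": len(ids),
                "n_pairs": len(pairs),
                "mean_r": float(pairs.mean()),
                "sd_r": float(pairs.std(ddof=1)) if len(pairs) > 1 else 0.0,
            }
        )
        group_means.append(pairs.mean())
    out = pd.DataFrame(rows, columns=["group", "n_samples", "n_pairs", "mean_r", "sd_r"])
    if group_means:
        out.loc[len(out)] = {
            "group": "__overall__",
            "n_samples": int(out["n_samples"].sum()),
            "n_pairs": int(out["n_pairs"].sum()),
            "mean_r": float(np.mean(group_means)),
            "sd_r": float(np.std(group_means, ddof=1)) if len(group_means) > 1 else 0.0,
        }
    return out


def high_gene_set(
    cpm: ExpressionMatrix,
    labels: LabelTable,
    organ: str,
    ratio: float = 10.0,
    baseline: str = "per_gene",
) -> set:
    """Genes "high" in ``organ``: organ mean exceeds ``ratio`` x the baseline.

    ``baseline="per_gene"`` compares each gene's organ mean to that gene's
    mean across all samples of the dataset (an enrichment ratio);
    ``baseline="whole_matrix"`` compares to the grand mean of the matrix.
    """
    lab = labels.table.loc[[s for s in cpm.sample_ids if s in labels.table.index]]
    organ_samples = list(lab.index[lab["class_label"] == organ])
    if not organ_samples:
        raise KeyError(f"organ {organ!r} absent from dataset")
    organ_mean = cpm.data[organ_samples].mean(axis=1)
    if baseline == "per_gene":
        base = cpm.data.mean(axis=1)
    elif baseline == "whole_matrix":
        base = pd.Series(cpm.values.mean(), index=cpm.data.index)
    else:
        raise ValueError("baseline must be 'per_gene' or 'whole_matrix'")
    return set(organ_mean.index[organ_mean > ratio * base])


@dataclass
class StagePartition:
    """Disjoint partition of an organ's high genes by stage membership."""

    organ: str
    stages: list
    parts: dict  # frozenset of stage names -> set of genes

    def unique_to(self, stage: str) -> set:
        return set(self.parts.get(frozenset([stage]), set()))

    def common_to_all(self) -> set:
        return set(self.parts.get(frozenset(self.stages), set()))

    def union(self) -> set:
        return {g for genes in self.parts.values() for g in genes}


def stage_specific_genes(
    stage_sets: Sequence[Tuple[str, ExpressionMatrix, LabelTable]],
    organ: str,
    ratio: float = 10.0,
    baseline: str = "per_gene",
) -> StagePartition:
    """Partition an organ's high genes by the stage datasets they appear in.

    Each element of ``stage_sets`` is (stage name, CPM matrix, labels).
    Datasets lacking the organ are dropped with a warning; at least two
    must remain.
    """
    high = {}
    for stage, m, labels in stage_sets:
        try:
            high[stage] = high_gene_set(m, labels, organ, ratio, baseline)
        except KeyError:
            logger.warning("organ %r absent from stage dataset %r; dropped", organ, stage)
    if len(high) < 2:
        raise ValueError(f"organ {organ!r} present in fewer than two stage datasets")
    parts: dict = {}
    for g in set().union(*high.values()):
        member = frozenset(s for s, genes in high.items() if g in genes)
        parts.setdefault(member, set()).add(g)
    return StagePartition(organ=organ, stages=list(high), parts=parts)
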