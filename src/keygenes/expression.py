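"""Core in-memory containers: expression matrices, label tables, gene panels.

All downstream steps operate on :class:`ExpressionMatrix` (genes in rows,
samples in columns) and :class:`LabelTable` (sample -> tissue class, optional
developmental stage).  Gene and sample namespaces are plain strings compared
by equality; no identifier translation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORMS = ("counts", "cpm", "intensity")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix with a platform tag.

    Parameters
    ----------
    data
        DataFrame with gene IDs as the index and sample IDs as columns.
        Values must be non-negative, and integral when ``platform="counts"``.
    platform
        One of ``"counts"`` (raw NGS read counts), ``"cpm"`` (counts per
        million, possibly TMM-adjusted) or ``"intensity"`` (microarray
        fluorescence intensities).
    meta
        Free-form provenance map (source file, normalization applied, ...).
    """

    data: pd.DataFrame
    platform: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        values = self.data.to_numpy()
        if values.size and np.nanmin(values) < 0:
            g, s = np.unravel_index(np.nanargmin(values), values.shape)
            raise ValueError(
                f"negative value {values[g, s]} at gene {idx[g]!r}, sample {cols[s]!r}"
            )
        if np.isnan(values).any():
            g, s = np.unravel_index(int(np.argmax(np.isnan(values))), values.shape)
            raise ValueError(f"missing value at gene {idx[g]!r}, sample {cols[s]!r}")
        if self.platform == "counts" and values.size:
            if not np.allclose(values, np.round(values)):
                g, s = np.unravel_index(
                    int(np.argmax(~np.isclose(values, np.round(values)))), values.shape
                )
                raise ValueError(
                    f"platform='counts' requires integer values; found "
                    f"{values[g, s]} at gene {idx[g]!r}, sample {cols[s]!r}"
                )

    # -- accessors -----------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def library_sizes(self) -> pd.Series:
        """Total counts per sample (column sums)."""
        return self.data.sum(axis=0)

    # -- manipulation --------------------------------------------------
    def select_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.platform, dict(self.meta))

    def select_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)], self.platform, dict(self.meta))

    def with_meta(self, **kv: str) -> "ExpressionMatrix":
        meta = dict(self.meta)
        meta.update(kv)
        return ExpressionMatrix(self.data, self.platform, meta)


@dataclass
class LabelTable:
    """Sample -> (tissue class, optional stage) mapping."""

    table: pd.DataFrame  # index: sample_id; columns: class_label, stage

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs in label table: {dupes[:5]}")
        if "class_label" not in self.table.columns:
            raise ValueError("label table needs a 'class_label' column")
        if "stage" not in self.table.columns:
            self.table = self.table.assign(stage=None)
        cl = self.table["class_label"].astype(str).str.strip()
        if (cl == "").any():
            bad = self.table.index[cl == ""].tolist()
            raise ValueError(f"empty class label for samples: {bad[:5]}")
        self.table = self.table.assign(class_label=cl)

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, str] | Mapping[str, Tuple[str, Optional[str]]]
    ) -> "LabelTable":
        rows = {}
        for sid, val in mapping.items():
            if isinstance(val, tuple):
                rows[sid] = {"class_label": val[0], "stage": val[1]}
            else:
                rows[sid] = {"class_label": val, "stage": None}
        return cls(pd.DataFrame.from_dict(rows, orient="index"))

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def classes(self) -> list:
        return sorted(self.table["class_label"].unique())

    def class_of(self, sample_id: str) -> str:
        return self.table.at[sample_id, "class_label"]

    def stage_of(self, sample_id: str) -> Optional[str]:
        v = self.table.at[sample_id, "stage"]
        return None if pd.isna(v) else v

    def labels_for(self, sample_ids: Sequence[str]) -> pd.Series:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples without labels: {missing[:5]}")
        return self.table.loc[list(sample_ids), "class_label"]

    def subset(self, sample_ids: Sequence[str]) -> "LabelTable":
        return LabelTable(self.table.loc[list(sample_ids)].copy())

    def warn_small_classes(self, minimum: int = 2) -> list:
        """Classes with fewer than ``minimum`` samples (CV degenerates)."""
        counts = self.table["class_label"].value_counts()
        small = sorted(counts.index[counts < minimum])
        if small:
            logger.warning(
                "classes with < %d training samples (cross-validation degenerates): %s",
                minimum,
                small,
            )
        return small


@dataclass
class GenePanel:
    """Named ordered list of gene IDs (e.g. a housekeeping panel)."""

    gene_ids: list
    name: str = "panel"

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("empty gene panel")
        seen = set()
        for g in self.gene_ids:
            if g in seen:
                raise ValueError(f"duplicate gene in panel: {g!r}")
            seen.add(g)

    def __len__(self) -> int:
        return len(self.gene_ids)


def align_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> Tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to their common genes, in identical order.

    The shared order follows the first argument.  Raises if the gene
    namespaces are disjoint (usually an identifier-scheme mismatch).
    """
    if a.n_genes == 0 or b.n_genes == 0:
        raise ValueError("cannot align an empty matrix")
    b_set = set(b.gene_ids)
    common = [g for g in a.gene_ids if g in b_set]
    if not common:
        raise ValueError(
            "no genes in common between the two matrices; "
            "check that both use the same gene identifier namespace"
        )
    logger.info("align_genes: %d common genes (a: %d, b: %d)", len(common), a.n_genes, b.n_genes)
    return a.select_genes(common), b.select_genes(common)
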