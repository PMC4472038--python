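"""Reading and writing the delimited-text formats the pipeline touches.

Expression matrices are plain TSV/CSV with gene IDs in the first column and a
header row of sample IDs.  Label tables are two- or three-column delimited
files (sample, class[, stage]).  Gene panels are one ID per line.  Floats are
written with 12 significant digits so a write/read round trip is lossless at
working precision.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GenePanel, LabelTable

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


def _sniff_delimiter(header_line: str) -> str:
    # tab preferred when both occur
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    return "\t"


def read_expression_table(
    path: str | Path,
    platform: str,
    delimiter: Optional[str] = None,
) -> ExpressionMatrix:
    """Read a gene-by-sample matrix from delimited text.

    Duplicate gene rows are collapsed — summed for counts (read counts are
    additive), averaged otherwise (array probes map many-to-one to genes) —
    with a warning.  Duplicate sample IDs are a hard error.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if delimiter is None:
        delimiter = _sniff_delimiter(header)
    header_fields = header.split(delimiter)
    sample_ids = [f.strip() for f in header_fields[1:]]
    seen = set()
    for sid in sample_ids:
        if sid in seen:
            raise ValueError(f"duplicate sample ID in {path.name}: {sid!r}")
        seen.add(sid)

    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    raw.columns = [c.strip() for c in raw.columns]
    raw.index = raw.index.astype(str).str.strip()
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.unravel_index(int(np.argmax(bad.to_numpy())), bad.shape)
        raise ValueError(
            f"malformed numeric value {raw.iloc[g, s]!r} at gene "
            f"{raw.index[g]!r}, sample {raw.columns[s]!r} in {path.name}"
        )
    if numeric.isna().to_numpy().any():
        g, s = np.unravel_index(int(np.argmax(numeric.isna().to_numpy())), numeric.shape)
        raise ValueError(
            f"missing value at gene {numeric.index[g]!r}, sample "
            f"{numeric.columns[s]!r} in {path.name}"
        )
    neg = numeric.to_numpy() < 0
    if neg.any():
        g, s = np.unravel_index(int(np.argmax(neg)), neg.shape)
        raise ValueError(
            f"negative value {numeric.iloc[g, s]} at gene {numeric.index[g]!r}, "
            f"sample {numeric.columns[s]!r} in {path.name}"
        )

    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        how = "sum" if platform == "counts" else "mean"
        logger.warning(
            "%s: %d duplicated gene rows collapsed by %s", path.name, n_dup, how
        )
        grouped = numeric.groupby(level=0, sort=False)
        numeric = grouped.sum() if platform == "counts" else grouped.mean()

    return ExpressionMatrix(numeric, platform, {"source": str(path)})


def write_expression_table(m: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = m.data
    if m.platform == "counts":
        df = df.round().astype(np.int64)
        df.to_csv(path, sep=delimiter)
    else:
        df.to_csv(path, sep=delimiter, float_format=FLOAT_FORMAT)


_LABEL_HEADER_TOKENS = {"sample", "sample_id", "sampleid", "id", "class", "class_label", "tissue"}


def read_label_table(path: str | Path) -> LabelTable:
    """Read a sample/class[/stage] table; a header row is auto-detected."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    delimiter = _sniff_delimiter(first)
    fields = [f.strip() for f in first.split(delimiter)]
    has_header = any(f.lower() in _LABEL_HEADER_TOKENS for f in fields[:2])
    df = pd.read_csv(
        path, sep=delimiter, header=0 if has_header else None, dtype=str
    )
    if df.shape[1] not in (2, 3):
        raise ValueError(
            f"{path.name}: expected 2 or 3 columns (sample, class[, stage]), got {df.shape[1]}"
        )
    df.columns = ["sample_id", "class_label", "stage"][: df.shape[1]]
    df["sample_id"] = df["sample_id"].str.strip()
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs in {path.name}: {dupes[:5]}")
    if df["class_label"].isna().any() or (df["class_label"].str.strip() == "").any():
        bad = df.loc[
            df["class_label"].isna() | (df["class_label"].str.strip() == ""), "sample_id"
        ].tolist()
        raise ValueError(f"empty class label in {path.name} for samples: {bad[:5]}")
    if "stage" in df.columns:
        df["stage"] = df["stage"].str.strip()
    return LabelTable(df.set_index("sample_id"))


def write_label_table(labels: LabelTable, path: str | Path) -> None:
    df = labels.table.reset_index()
    df.columns = ["sample_id", "class_label", "stage"][: df.shape[1]]
    if df["stage"].isna().all():
        df = df[["sample_id", "class_label"]]
    df.to_csv(path, sep="\t", index=False)


def read_gene_panel(path: str | Path, name: Optional[str] = None) -> GenePanel:
    """One gene ID per line; blank lines and '#' comments skipped."""
    path = Path(path)
    genes = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return GenePanel(genes, name or path.stem)


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Identity-score matrix (classes x samples) as TSV."""
    scores.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
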