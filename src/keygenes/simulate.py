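"""Synthetic expression atlas with planted ground truth.

Emulates the structure of a multi-tissue, two-trimester bulk RNA-seq atlas:
negative-binomial counts with per-sample library-size factors, a disjoint
set of marker genes per tissue elevated by a known fold change (optionally
stage-modulated, so a marker can be moderately expressed in the first
trimester and strongly in the second), and a designated set of stably
expressed housekeeping genes.  A companion generator derives microarray-like
intensities from the counts via an affine distortion of log expression plus
Gaussian noise and probe subsampling.

Every structural choice is drawn from the seed stored on
:class:`SimulationTruth`, and the truth object serializes to JSON, so any
fixture can be replayed exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GenePanel, LabelTable

DEFAULT_TISSUES = (
    "brain", "heart", "liver", "kidney", "lung", "pancreas", "muscle", "skin",
)


@dataclass
class SimulationTruth:
    """Ground-truth parameters of a synthetic atlas."""

    tissues: list
    stages: list
    gene_ids: list
    markers: dict            # tissue -> list of gene IDs
    housekeepers: list
    baseline_means: np.ndarray
    marker_fold: float
    stage_fold: dict         # stage -> multiplier applied to marker fold
    dispersion: float
    library_scale_range: Tuple[float, float]
    seed: int

    def __post_init__(self) -> None:
        self.baseline_means = np.asarray(self.baseline_means, dtype=float)
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.marker_fold <= 0:
            raise ValueError("marker fold-change must be positive")
        if len(self.baseline_means) != len(self.gene_ids):
            raise ValueError("baseline_means length must match gene_ids")

    # -- construction --------------------------------------------------
    @classmethod
    def default(
        cls,
        tissues: Sequence[str] = DEFAULT_TISSUES,
        stages: Sequence[str] = ("1T", "2T"),
        n_genes: int = 2000,
        markers_per_tissue: int = 20,
        n_shared_markers: int = 0,
        n_housekeepers: int = 300,
        marker_fold: float = 32.0,
        stage_fold: Optional[dict] = None,
        dispersion: float = 0.1,
        library_scale_range: Tuple[float, float] = (0.7, 1.3),
        mean_library_size: float = 1_000_000.0,
        seed: int = 0,
    ) -> "SimulationTruth":
        """Atlas-like defaults: 8 tissues, 20 disjoint markers each, 32-fold
        elevation, NB dispersion 0.1, ~1e6 reads per sample."""
        rng = np.random.default_rng(seed)
        tissues = list(tissues)
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]

        needed = len(tissues) * markers_per_tissue + n_shared_markers + n_housekeepers
        if needed > n_genes:
            raise ValueError("not enough genes for the requested markers/housekeepers")
        special = rng.choice(n_genes, size=needed, replace=False)
        pos = 0
        markers = {}
        for t in tissues:
            markers[t] = sorted(gene_ids[i] for i in special[pos : pos + markers_per_tissue])
            pos += markers_per_tissue
        # shared markers belong to two consecutive tissues (multi-class barcode genes)
        for j in range(n_shared_markers):
            g = gene_ids[special[pos]]
            markers[tissues[j % len(tissues)]].append(g)
            markers[tissues[(j + 1) % len(tissues)]].append(g)
            pos += 1
        housekeepers = sorted(gene_ids[i] for i in special[pos : pos + n_housekeepers])

        base = rng.lognormal(mean=np.log(30.0), sigma=1.4, size=n_genes)
        hk_idx = [gene_ids.index(g) for g in housekeepers]
        base[hk_idx] = rng.lognormal(mean=np.log(150.0), sigma=0.4, size=len(hk_idx))
        base *= mean_library_size / base.sum()

        return cls(
            tissues=tissues,
            stages=list(stages),
            gene_ids=gene_ids,
            markers=markers,
            housekeepers=housekeepers,
            baseline_means=base,
            marker_fold=marker_fold,
            stage_fold=dict(stage_fold or {s: 1.0 for s in stages}),
            dispersion=dispersion,
            library_scale_range=library_scale_range,
            seed=seed,
        )

    def housekeeper_panel(self, name: str = "synthetic_housekeepers") -> GenePanel:
        return GenePanel(list(self.housekeepers), name)

    def marker_union(self) -> set:
        return {g for genes in self.markers.values() for g in genes}

    # -- replay --------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["baseline_means"] = self.baseline_means.tolist()
        d["library_scale_range"] = list(self.library_scale_range)
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        d["baseline_means"] = np.asarray(d["baseline_means"])
        d["library_scale_range"] = tuple(d["library_scale_range"])
        return cls(**d)


def simulate_tissue_counts(
    truth: SimulationTruth,
    samples_per_tissue: int = 5,
    seed: int = 0,
) -> Tuple[ExpressionMatrix, LabelTable]:
    """Draw negative-binomial counts for every tissue.

    Marker genes of a tissue have their mean multiplied by
    ``marker_fold * stage_fold[stage]`` in that tissue's samples; stages are
    assigned round-robin within each tissue.  Counts are
    ``NB(r = 1/dispersion, mean = baseline * library_scale)``.
    """
    if len(truth.tissues) < 2:
        raise ValueError("need at least two tissues")
    if samples_per_tissue < 1:
        raise ValueError("need at least one sample per tissue")
    rng = np.random.default_rng(seed)
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    lo, hi = truth.library_scale_range
    r = 1.0 / truth.dispersion

    columns = {}
    label_rows = {}
    for tissue in truth.tissues:
        marker_idx = np.array([gene_index[g] for g in truth.markers.get(tissue, [])], dtype=int)
        for si in range(samples_per_tissue):
            stage = truth.stages[si % len(truth.stages)] if truth.stages else None
            lib_scale = rng.uniform(lo, hi)
            mu = truth.baseline_means * lib_scale
            if marker_idx.size:
                fold = truth.marker_fold * truth.stage_fold.get(stage, 1.0)
                mu = mu.copy()
                mu[marker_idx] *= fold
            counts = rng.negative_binomial(r, r / (r + mu))
            sid = f"{tissue}_s{si + 1}"
            columns[sid] = counts
            label_rows[sid] = {"class_label": tissue, "stage": stage}

    data = pd.DataFrame(columns, index=pd.Index(truth.gene_ids, name="gene_id"))
    labels = LabelTable(pd.DataFrame.from_dict(label_rows, orient="index"))
    meta = {"source": f"simulate_tissue_counts(seed={seed}, truth_seed={truth.seed})"}
    return ExpressionMatrix(data, "counts", meta), labels


def simulate_microarray(
    counts: ExpressionMatrix,
    truth: SimulationTruth,
    probe_fraction: float = 1.0,
    noise_sd: float = 0.0,
    gain: float = 1.0,
    offset: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Microarray-like intensities derived from simulated counts.

    ``intensity = 2 ** (gain * log2(CPM) + offset + N(0, noise_sd))`` for
    genes with nonzero CPM (zeros stay zero), on plain library-size CPM.
    Genes are subsampled to ``ceil(probe_fraction * n_genes)``, always
    keeping the housekeeping genes (real array designs cover them well).
    """
    if not 0 < probe_fraction <= 1:
        raise ValueError("probe_fraction must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if counts.platform != "counts":
        raise ValueError("simulate_microarray expects raw counts")
    rng = np.random.default_rng(seed)

    lib = counts.values.sum(axis=0)
    cpm_values = counts.values / lib * 1e6
    with np.errstate(divide="ignore"):
        log_cpm = np.log2(cpm_values, where=cpm_values > 0,
                          out=np.full_like(cpm_values, -np.inf))
    noise = rng.normal(0.0, noise_sd, size=log_cpm.shape) if noise_sd > 0 else 0.0
    with np.errstate(over="ignore"):
        intensities = np.where(
            cpm_values > 0, 2.0 ** (gain * log_cpm + offset + noise), 0.0
        )

    n_keep = int(np.ceil(probe_fraction * counts.n_genes))
    hk = [g for g in truth.housekeepers if g in set(counts.gene_ids)]
    if n_keep < len(hk):
        n_keep = len(hk)
    others = [g for g in counts.gene_ids if g not in set(hk)]
    extra = n_keep - len(hk)
    kept = set(hk) | set(rng.choice(others, size=extra, replace=False)) if extra else set(hk)
    keep_genes = [g for g in counts.gene_ids if g in kept]

    df = pd.DataFrame(intensities, index=counts.data.index, columns=counts.data.columns)
    meta = {"source": f"simulate_microarray(seed={seed})",
            "probe_fraction": str(probe_fraction)}
    return ExpressionMatrix(df.loc[keep_genes], "intensity", meta)
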