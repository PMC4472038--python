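"""Detection filtering, TMM normalization and counts-per-million.

Between-sample normalization uses the weighted trimmed mean of M-values
(TMM): for each sample a scale factor is computed from pairwise log ratios
against a reference sample, after discarding genes that are extreme in
either log fold-change (M) or average abundance (A), weighting the rest by
inverse delta-method binomial variances.  Factors are rescaled to geometric
mean 1, and CPM divides counts by the effective library size
(library size x TMM factor) times 1e6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizationFactors:
    """Per-sample library sizes and TMM scale factors.

    The product of ``tmm_factors`` is 1 (geometric-mean convention), so CPM
    values stay on a comparable absolute scale across runs.
    """

    sample_ids: list
    library_sizes: np.ndarray
    tmm_factors: np.ndarray
    reference_sample: str

    def __post_init__(self) -> None:
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        self.tmm_factors = np.asarray(self.tmm_factors, dtype=float)
        if np.any(self.library_sizes <= 0):
            raise ValueError("library sizes must be positive")
        if np.any(self.tmm_factors <= 0):
            raise ValueError("TMM factors must be positive")
        log_prod = np.sum(np.log(self.tmm_factors))
        if abs(log_prod) > 1e-9 * max(1, len(self.tmm_factors)):
            raise ValueError("TMM factors must have product 1 (geometric mean 1)")

    def factor_for(self, sample_id: str) -> float:
        return float(self.tmm_factors[self.sample_ids.index(sample_id)])

    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.tmm_factors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lib_size": self.library_sizes.astype(np.int64),
                "tmm_factor": self.tmm_factors,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def filter_detected(m: ExpressionMatrix, cutoff: int = 4) -> ExpressionMatrix:
    """Drop genes below the detection limit.

    A gene is kept when it reaches at least ``cutoff`` reads in at least one
    sample; below four reads a gene is treated as undetected.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if m.platform != "counts":
        raise ValueError("filter_detected expects raw counts")
    keep = (m.data >= cutoff).any(axis=1)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_detected: removed %d of %d genes below %d reads",
                    removed, m.n_genes, cutoff)
    return ExpressionMatrix(m.data.loc[keep], m.platform, dict(m.meta))


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
    weighted: bool = True,
) -> float:
    """TMM factor of one sample against the reference (2^weighted trimmed mean M)."""
    obs = obs.astype(float)
    ref = ref.astype(float)
    n_o = obs.sum()
    n_r = ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_o) / (ref / n_r))          # M values
        abs_e = (np.log2(obs / n_o) + np.log2(ref / n_r)) / 2.0  # A values
        v = (n_o - obs) / (n_o * obs) + (n_r - ref) / (n_r * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    return float(2.0 ** f)


def compute_tmm_factors(
    m: ExpressionMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> NormalizationFactors:
    """Weighted trimmed mean of M-values normalization factors.

    The reference sample is the one whose 75th percentile of library-size-
    scaled counts is closest to the mean of those percentiles.  For every
    sample, genes with zero counts in either the sample or the reference are
    excluded, the top and bottom ``trim_m`` of M-values and ``trim_a`` of
    A-values are trimmed, and the remaining M-values are averaged with
    inverse-variance weights.  Factors are rescaled to geometric mean 1.
    """
    if m.platform != "counts":
        raise ValueError("TMM normalization expects raw counts")
    if m.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    counts = m.values
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        bad = [m.sample_ids[i] for i in np.nonzero(lib <= 0)[0]]
        raise ValueError(f"samples with zero total counts: {bad}")

    scaled = counts / lib
    f75 = np.quantile(scaled, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = counts[:, ref_idx]

    factors = np.array(
        [
            1.0
            if i == ref_idx
            else _tmm_pair_factor(counts[:, i], ref, trim_m, trim_a, weighted)
            for i in range(m.n_samples)
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    logger.info(
        "TMM: reference sample %s; factor range [%.4f, %.4f]",
        m.sample_ids[ref_idx], factors.min(), factors.max(),
    )
    return NormalizationFactors(
        sample_ids=m.sample_ids,
        library_sizes=lib,
        tmm_factors=factors,
        reference_sample=m.sample_ids[ref_idx],
    )


def cpm(
    m: ExpressionMatrix,
    factors: NormalizationFactors | None = None,
    log2_out: bool = False,
    prior: float = 1.0,
) -> ExpressionMatrix:
    """Counts per million over effective library sizes.

    ``value = count / (library_size * tmm_factor) * 1e6``; with ``log2_out``
    the result is ``log2(CPM + prior)``.  When ``factors`` is omitted the
    TMM factors are computed on the fly.
    """
    if m.platform != "counts":
        raise ValueError("cpm expects raw counts")
    if factors is None:
        factors = compute_tmm_factors(m)
    missing = [s for s in m.sample_ids if s not in factors.sample_ids]
    if missing:
        raise ValueError(f"normalization factors missing for samples: {missing[:5]}")
    order = [factors.sample_ids.index(s) for s in m.sample_ids]
    eff = factors.effective_library_sizes()[order]
    values = m.values / eff * 1e6
    if log2_out:
        values = np.log2(values + prior)
    if log2_out and prior < 1:
        raise ValueError("prior must be >= 1 so log2(CPM + prior) stays non-negative")
    out = pd.DataFrame(values, index=m.data.index, columns=m.data.columns)
    meta = dict(m.meta)
    meta["normalization"] = "log2(CPM+%g)" % prior if log2_out else "CPM"
    return ExpressionMatrix(out, "cpm", meta)
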