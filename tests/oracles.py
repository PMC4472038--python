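"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a quantity from its definition with naive code
(explicit loops, O(n^3) agglomeration, a generic convex solver) so that
agreement with the package is evidence of correctness, not of shared code.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# weighted trimmed mean of M-values, literal transcription
# ---------------------------------------------------------------------------

def _avg_rank(values):
    """1-based ranks with ties averaged (no library call)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def tmm_factors_bruteforce(counts, trim_m=0.30, trim_a=0.05):
    """TMM factors computed literally from the definition.

    counts: (genes, samples) integer array.  Returns factors with
    geometric mean 1 and the reference column index.
    """
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    lib = counts.sum(axis=0)

    # reference: 75th percentile of counts/libsize closest to the mean
    f75 = [np.quantile(counts[:, s] / lib[s], 0.75) for s in range(n_samples)]
    mean75 = sum(f75) / n_samples
    ref = min(range(n_samples), key=lambda s: abs(f75[s] - mean75))

    factors = []
    for s in range(n_samples):
        if s == ref:
            factors.append(1.0)
            continue
        m_vals, a_vals, weights = [], [], []
        for g in range(n_genes):
            o, r = counts[g, s], counts[g, ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / lib[s], r / lib[ref]
            m_vals.append(np.log2(po / pr))
            a_vals.append((np.log2(po) + np.log2(pr)) / 2.0)
            weights.append(
                1.0 / ((lib[s] - o) / (lib[s] * o) + (lib[ref] - r) / (lib[ref] * r))
            )
        if not m_vals or max(abs(m) for m in m_vals) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m_vals)
        lo_m = int(np.floor(n * trim_m)) + 1
        hi_m = n + 1 - lo_m
        lo_a = int(np.floor(n * trim_a)) + 1
        hi_a = n + 1 - lo_a
        rank_m = _avg_rank(m_vals)
        rank_a = _avg_rank(a_vals)
        num = den = 0.0
        kept = 0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += m_vals[i] * weights[i]
                den += weights[i]
                kept += 1
        factors.append(2.0 ** (num / den) if kept else 1.0)

    factors = np.array(factors)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors, ref


# ---------------------------------------------------------------------------
# naive complete-linkage agglomeration
# ---------------------------------------------------------------------------

def complete_linkage_heights(dist):
    """Merge heights of naive O(n^3) complete-linkage clustering."""
    dist = np.asarray(dist, dtype=float)
    clusters = [[i] for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


# ---------------------------------------------------------------------------
# generic convex solver for the L1 multinomial objective (via sklearn saga)
# ---------------------------------------------------------------------------

def l1_multinomial_reference(X, y, lam, tol=1e-10, max_iter=1_000_000):
    """Coefficients/intercepts minimizing the penalized multinomial loss.

    Uses scikit-learn's saga solver (an optimizer unrelated to the
    package's proximal-gradient implementation) on the equivalent
    objective ``C * sum_loss + ||W||_1`` with ``C = 1/(n*lam)``.
    Intercepts are centered to sum zero (they are only identified up to a
    common shift).
    """
    from sklearn.linear_model import LogisticRegression

    n = X.shape[0]
    clf = LogisticRegression(
        l1_ratio=1.0, solver="saga", C=1.0 / (n * lam),
        tol=tol, max_iter=max_iter, random_state=0,
    )
    clf.fit(X, y)
    coef = clf.coef_
    icpt = clf.intercept_ - clf.intercept_.mean()
    return coef, icpt, clf.classes_


# ---------------------------------------------------------------------------
# set-algebra oracles
# ---------------------------------------------------------------------------

def housekeeper_selection_bruteforce(panel, train_cpm_df, test_genes, detection_cpm):
    out = []
    for g in panel:
        if g not in train_cpm_df.index:
            continue
        if g not in test_genes:
            continue
        if max(train_cpm_df.loc[g]) >= detection_cpm:
            out.append(g)
    return out


def high_genes_bruteforce(cpm_df, organ_samples, ratio):
    """Genes whose organ mean exceeds ratio x their dataset mean."""
    out = set()
    for g in cpm_df.index:
        organ_mean = sum(cpm_df.loc[g, s] for s in organ_samples) / len(organ_samples)
        dataset_mean = sum(cpm_df.loc[g]) / cpm_df.shape[1]
        if organ_mean > ratio * dataset_mean:
            out.add(g)
    return out


def top_variable_bruteforce(values_df, n, log_transform=True):
    """Per-gene variance sort with lexicographic tie-break."""
    scored = []
    for g in values_df.index:
        v = np.asarray(values_df.loc[g], dtype=float)
        if log_transform:
            v = np.log2(v + 1.0)
        mean = v.mean()
        var = ((v - mean) ** 2).sum() / (len(v) - 1)
        scored.append((g, var))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in scored[:n]]
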