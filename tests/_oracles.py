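"""Independent brute-force oracles used by the test suite.

Deliberately written as plain loops, separate from the vectorized
implementations they check.
"""

import math

import numpy as np


def _avg_ranks(vals):
    ranks = []
    for v in vals:
        less = sum(1 for u in vals if u < v)
        eq = sum(1 for u in vals if u == v)
        ranks.append(less + (eq + 1) / 2.0)
    return ranks


def tmm_oracle(counts, trim_m=0.30, trim_a=0.05, ref_idx=None):
    """Brute-force TMM factors for a genes x samples integer array.

    Enumerates M/A values gene by gene, trims both tails by rank, and
    computes the precision-weighted mean of the surviving M values.
    """
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    totals = [counts[:, j].sum() for j in range(n_samples)]
    if ref_idx is None:
        fracs = [sorted(counts[:, j] / totals[j]) for j in range(n_samples)]
        q75 = []
        for f in fracs:
            q75.append(float(np.quantile(f, 0.75)))
        mean_q = sum(q75) / n_samples
        ref_idx = min(range(n_samples), key=lambda j: (abs(q75[j] - mean_q), j))
    log_factors = []
    for j in range(n_samples):
        if j == ref_idx:
            log_factors.append(0.0)
            continue
        ms, aas, ws = [], [], []
        for g in range(n_genes):
            o, r = counts[g, j], counts[g, ref_idx]
            if o > 0 and r > 0:
                po, pr = o / totals[j], r / totals[ref_idx]
                ms.append(math.log2(po / pr))
                aas.append(0.5 * math.log2(po * pr))
                ws.append(
                    (totals[j] - o) / (totals[j] * o)
                    + (totals[ref_idx] - r) / (totals[ref_idx] * r)
                )
        n = len(ms)
        if n == 0:
            log_factors.append(0.0)
            continue
        rm, ra = _avg_ranks(ms), _avg_ranks(aas)
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        num = den = 0.0
        for m, a_rank, m_rank, w in zip(ms, ra, rm, ws):
            if lo_m <= m_rank <= hi_m and lo_a <= a_rank <= hi_a:
                num += m / w
                den += 1.0 / w
        log_factors.append(num / den if den > 0 else 0.0)
    factors = [2.0**f for f in log_factors]
    geo = math.exp(sum(math.log(f) for f in factors) / n_samples)
    return [f / geo for f in factors], ref_idx


def bh_oracle(pvals):
    """Textbook Benjamini-Hochberg adjusted p-values."""
    p = list(pvals)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running_min = 1.0
    for rank_from_end in range(n, 0, -1):
        i = order[rank_from_end - 1]
        val = p[i] * n / rank_from_end
        running_min = min(running_min, val)
        adj[i] = min(running_min, 1.0)
    return adj


def one_se_oracle(mtrys, rmses, ses):
    """One-SE rule by direct enumeration."""
    best = min(range(len(rmses)), key=lambda i: rmses[i])
    thr = rmses[best] + ses[best]
    eligible = [m for m, r in zip(mtrys, rmses) if r <= thr]
    return min(eligible)


def venn_oracle(sets_by_label):
    """All intersection-minus-union region counts by direct set algebra."""
    labels = list(sets_by_label)
    out = {}
    for mask in range(1, 2 ** len(labels)):
        inside = tuple(l for i, l in enumerate(labels) if mask >> i & 1)
        outside = [l for l in labels if l not in inside]
        region = set.intersection(*(sets_by_label[l] for l in inside))
        for l in outside:
            region -= sets_by_label[l]
        out[inside] = len(region)
    return out
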