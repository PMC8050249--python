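"""Independent brute-force reference implementations used only by tests.

Every function here is deliberately naive (per-base masks, all-pairs
scans, union-find, direct formulas) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def merge_union_find(records):
    """records: (chrom, start, end, sample). Returns sorted list of
    (chrom, start, end, frozenset(samples)) merged at >=1 bp overlap."""
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei, _ = records[i]
            cj, sj, ej, _ = records[j]
            if ci == cj and si < ej and sj < ei:
                union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        chrom = records[members[0]][0]
        start = min(records[m][1] for m in members)
        end = max(records[m][2] for m in members)
        samples = frozenset(records[m][3] for m in members)
        out.append((chrom, start, end, samples))
    return sorted(out)


def nearest_all_pairs(peak, genes):
    """peak: (chrom, start, end); genes: (gene_id, chrom, start, end).
    Returns (gene_id or None, |distance|) by exhaustive minimum with the
    leftmost-start then smallest-id tie rule."""
    best = None
    for gid, c, s, e in genes:
        if c != peak[0]:
            continue
        if peak[1] < e and s < peak[2]:
            d = 0
        elif peak[2] <= s:
            d = s - peak[2]
        else:
            d = peak[1] - e
        key = (d, s, gid)
        if best is None or key < best:
            best = key
    if best is None:
        return None, 0
    return best[2], best[0]


def classify_by_windows(peak, tss_windows):
    """tss_windows: list of (chrom, lo, hi) half-open protein-coding TSS
    windows. Proximal iff the peak overlaps any of them."""
    for c, lo, hi in tss_windows:
        if c == peak[0] and peak[1] < hi and lo < peak[2]:
            return "proximal"
    return "distal"


def effective_kb_per_base(window, exclusions):
    """Per-base boolean mask count of the non-excluded window bases."""
    chrom, start, end = window
    mask = np.zeros(end - start, dtype=bool)
    for c, s, e in exclusions:
        if c != chrom:
            continue
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            mask[lo - start: hi - start] = True
    return (len(mask) - int(mask.sum())) / 1000.0


def nearest_window_state(peak_center, windows):
    """windows: (start, end, state) on the peak's chromosome. Minimum
    |center - midpoint| with lower-coordinate tie break."""
    best = None
    for s, e, state in windows:
        mid = (s + e) // 2
        key = (abs(peak_center - mid), s)
        if best is None or key < best[0]:
            best = (key, state)
    return None if best is None else best[1]


def enrichment_of_proportions(n_diff, k_diff, n_nondiff, k_nondiff):
    return (k_diff / n_diff) / (k_nondiff / n_nondiff)


def chi2_scipy(k_diff, n_diff, k_nondiff, n_nondiff):
    obs = [[k_diff, n_diff - k_diff], [k_nondiff, n_nondiff - k_nondiff]]
    res = stats.chi2_contingency(obs, correction=False)
    return float(res[0]), float(res[1])


def quantile_normalize_naive(x):
    """Column-wise quantile normalization to the mean of sorted columns."""
    x = np.asarray(x, dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        for rank, i in enumerate(order):
            out[i, j] = ref[rank]
    return out


def poisson_double_tail(s1, s2, n1, n2):
    """Exhaustive two-sided conditional test at phi = 0: the split of the
    total between groups is binomial with p = n1/(n1+n2)."""
    s = s1 + s2
    if s == 0:
        return 1.0
    p = n1 / (n1 + n2)
    probs = stats.binom.pmf(np.arange(s + 1), s, p)
    obs = probs[s1]
    return float(probs[probs <= obs * (1 + 1e-9)].sum() / probs.sum())


def track_counts_brute(reads, chrom_length, width, step):
    """Per-window overlap counts by direct scan."""
    n = (chrom_length - width) // step + 1
    out = np.zeros(n)
    for i in range(n):
        ws, we = i * step, i * step + width
        for s, e in reads:
            if s < we and ws < e:
                out[i] += 1
    return out
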