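"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: merging and overlap work
on per-base occupancy arrays, the ranked-curve cutoff is a plain scan over
every rank, and counting is a per-fragment loop.
"""

from __future__ import annotations

import numpy as np


def per_base_merge(intervals, gap, chrom_len=20_000):
    """Merge via a per-base occupancy array: mark covered bases, then join
    runs separated by <= gap uncovered bases.  Returns [(chrom, start, end)]."""
    out = []
    for chrom in sorted({iv.chrom for iv in intervals}):
        cov = np.zeros(chrom_len, dtype=bool)
        for iv in intervals:
            if iv.chrom == chrom:
                cov[iv.start : iv.end] = True
        runs = []
        i = 0
        while i < chrom_len:
            if cov[i]:
                j = i
                while j < chrom_len and cov[j]:
                    j += 1
                runs.append([i, j])
                i = j
            else:
                i += 1
        merged = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        out.extend((chrom, s, e) for s, e in merged)
    return out


def per_base_overlap(a_intervals, b_intervals, min_overlap=1, chrom_len=20_000):
    """hit[i] via per-base set intersection of a[i] with the union of b."""
    b_cov = {}
    for iv in b_intervals:
        cov = b_cov.setdefault(iv.chrom, np.zeros(chrom_len, dtype=bool))
        cov[iv.start : iv.end] = True
    hits = []
    for iv in a_intervals:
        cov = b_cov.get(iv.chrom)
        if cov is None:
            hits.append(False)
            continue
        # require min_overlap shared bases with at least one single b interval
        best = 0
        for bv in b_intervals:
            if bv.chrom != iv.chrom:
                continue
            shared = max(0, min(iv.end, bv.end) - max(iv.start, bv.start))
            best = max(best, shared)
        hits.append(best >= min_overlap)
    return np.array(hits, dtype=bool)


def slope_scan_cutoff(scores):
    """Scan every rank of the rescaled curve; first slope > 1 wins."""
    scores = list(map(float, scores))
    n = len(scores)
    smax = max(scores)
    if smax <= 0 or min(scores) == smax:
        return smax
    x = [(i + 1) / n for i in range(n)]
    y = [s / smax for s in scores]
    for i in range(n - 1):
        slope = (y[i + 1] - y[i]) / (x[i + 1] - x[i])
        if slope > 1.0:
            return scores[i]
    return smax


def midpoint_count(fragments, region):
    """Per-fragment loop: midpoints inside the half-open region."""
    c = 0
    for f in fragments:
        if f.chrom != region.chrom:
            continue
        mid = (f.start + f.end) // 2
        if region.start <= mid < region.end:
            c += 1
    return c


def exact_binom_two_sided(k, n, p):
    """Two-sided exact binomial p as the minlike tail sum."""
    from math import comb

    pk = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    obs = pk[k]
    return min(1.0, sum(x for x in pk if x <= obs * (1 + 1e-12)))
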