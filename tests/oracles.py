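"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library code paths they check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def texture_oracle(sample, n_bins=128):
    """Direct-summation first-order features (no vectorized moment tricks)."""
    xs = [float(v) for v in np.asarray(sample).ravel()]
    n = len(xs)
    mu = sum(xs) / n
    m2 = sum((x - mu) ** 2 for x in xs) / n
    if m2 == 0.0:
        return mu, 0.0, 0.0, 0.0, 0.0
    m3 = sum((x - mu) ** 3 for x in xs) / n
    m4 = sum((x - mu) ** 4 for x in xs) / n
    lo, hi = min(xs), max(xs)
    counts = [0] * n_bins
    width = (hi - lo) / n_bins
    for x in xs:
        b = min(int((x - lo) / width), n_bins - 1)
        counts[b] += 1
    entropy = -sum((c / n) * math.log2(c / n) for c in counts if c > 0)
    return mu, m2, m3 / m2**1.5, m4 / m2**2 - 3.0, entropy


def mannwhitney_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free inputs)."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    na = len(a)

    def u_of(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_of(a, b)
    n_total = 0
    n_extreme = 0
    nm = na * len(b)
    lo, hi = min(u_obs, nm - u_obs), max(u_obs, nm - u_obs)
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(ga, gb)
        n_total += 1
        if u <= lo or u >= hi:
            n_extreme += 1
    return u_obs, n_extreme / n_total


def auc_pair_counting(scores, labels):
    """AUC as the concordant-pair fraction, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def roi_members_bruteforce(shape, spacing, center, radius_mm):
    """Voxel-by-voxel disk membership enumeration."""
    members = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            d2 = ((i - center[0]) * spacing[0]) ** 2 + ((j - center[1]) * spacing[1]) ** 2
            if d2 <= radius_mm**2:
                members.append((i, j))
    return members
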