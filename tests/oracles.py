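"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, coded from the definitions (exact
rational arithmetic where possible), sharing no code with the package.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def wc_theta_exact(nA, pA_count, hA_count, nB, pB_count, hB_count):
    """Weir-Cockerham theta-hat for two populations in exact arithmetic.

    Counts instead of proportions keep everything rational: ``p*_count``
    is the derived-allele count out of ``2 n``, ``h*_count`` the number of
    heterozygous diploids out of ``n``. Returns a Fraction or None where
    undefined (a + b + c = 0).
    """
    nA, nB = Fraction(nA), Fraction(nB)
    pA, pB = Fraction(pA_count, 2 * int(nA)), Fraction(pB_count, 2 * int(nB))
    hA, hB = Fraction(hA_count, int(nA)), Fraction(hB_count, int(nB))
    r = Fraction(2)
    nbar = (nA + nB) / r
    nc = (r * nbar - (nA * nA + nB * nB) / (r * nbar)) / (r - 1)
    pbar = (nA * pA + nB * pB) / (r * nbar)
    s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (nA * hA + nB * hB) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    denom = a + b + c
    if denom == 0:
        return None
    return a / denom


def ehh_pair_counting(block: np.ndarray, core: int, target: int, subset, include_core: bool):
    """EHH at ``target`` by enumerating all haplotype pairs in ``subset``.

    Two haplotypes count as identical when they agree at every SNP in the
    inclusive span between ``core`` and ``target`` (the core column itself
    excluded unless ``include_core``).
    """
    lo, hi = min(core, target), max(core, target)
    cols = [j for j in range(lo, hi + 1) if include_core or j != core]
    rows = list(subset)
    n = len(rows)
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    same = 0
    for i, j in combinations(rows, 2):
        if all(block[i, c] == block[j, c] for c in cols):
            same += 1
    return Fraction(same, comb(n, 2))


def hypergeom_upper_tail_exact(k, n, K, N):
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact enumeration."""
    if k <= 0:
        return Fraction(1)
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return acc


def trapezoid_to_crossing(xs, ys, floor):
    """Piecewise-linear area from 0 out to the interpolated floor crossing."""
    area = 0.0
    for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
        if y1 < floor:
            xc = x0 + (y0 - floor) * (x1 - x0) / (y0 - y1)
            area += (y0 + floor) / 2 * (xc - x0)
            return area
        area += (y0 + y1) / 2 * (x1 - x0)
    return area
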