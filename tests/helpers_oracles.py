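"""Independent brute-force oracles used to cross-check the package.

Every function here recomputes a quantity from its definition (enumeration,
naive scanning, closed-form), deliberately sharing no code path with the
implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE = {("G", "U"), ("U", "G")}


def bh_bruteforce(p):
    """BH step-up straight from the definition: q_(i) = min_{j>=i} m p_(j)/j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


def hypergeom_enumerate(N, K, n, k):
    """P[X >= k] by exhaustive enumeration of all C(N, n) draws (N <= 12)."""
    universe = list(range(N))
    special = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total


def junction_counts_naive(reads, junctions, min_overhang, max_mismatches):
    """Sliding-window Hamming scan over every (read, junction) alignment offset."""
    counts = [0] * len(junctions)
    for ji, junction in enumerate(junctions):
        k = len(junction) // 2
        for read in reads:
            hit = False
            for o in range(-(len(read) - 1), 2 * k):
                a, b = max(0, o), min(2 * k, o + len(read))
                if a > k - min_overhang or b < k + min_overhang:
                    continue
                mm = sum(1 for i in range(a, b) if junction[i] != read[i - o])
                if mm <= max_mismatches:
                    hit = True
                    break
            if hit:
                counts[ji] += 1
    return counts


def miranda_recursive(window, mirna_seq, params):
    """Best local complementarity alignment score by memoized recursion."""
    x = window
    y = mirna_seq[::-1]
    L = len(mirna_seq)

    def pair_score(a, b, mirna_pos):
        if (a, b) in WC:
            s = params.match
        elif (a, b) in WOBBLE:
            s = params.wobble
        else:
            s = params.mismatch
        if 2 <= mirna_pos <= 8:
            s *= params.seed_weight
        return s

    @lru_cache(maxsize=None)
    def best_ending(i, j, state):
        # best score of an alignment ending at x[i-1], y[j-1] in the given state
        if i == 0 or j == 0:
            return -math.inf
        if state == "M":
            s = pair_score(x[i - 1], y[j - 1], L - (j - 1))
            prev = max(
                0.0,
                best_ending(i - 1, j - 1, "M"),
                best_ending(i - 1, j - 1, "X"),
                best_ending(i - 1, j - 1, "Y"),
            )
            return prev + s
        if state == "X":  # gap consuming x
            return max(
                best_ending(i - 1, j, "M") + params.gap_open,
                best_ending(i - 1, j, "X") + params.gap_extend,
            )
        return max(
            best_ending(i, j - 1, "M") + params.gap_open,
            best_ending(i, j - 1, "Y") + params.gap_extend,
        )

    best = 0.0
    for i in range(1, len(x) + 1):
        for j in range(1, len(y) + 1):
            best = max(best, best_ending(i, j, "M"))
    return best


def duplex_enumerate(xseq, yseq_53, params):
    """Duplex MFE by exhaustive enumeration of all non-crossing pair chains."""
    x = xseq
    y = yseq_53[::-1]

    def pairable(a, b):
        return (a, b) in WC or (a, b) in WOBBLE

    pairs = [(i, j) for i in range(len(x)) for j in range(len(y)) if pairable(x[i], y[j])]

    best = math.inf

    def energy(chain):
        e = params.init
        for (i1, j1), (i2, j2) in zip(chain, chain[1:]):
            a, b = i2 - i1 - 1, j2 - j1 - 1
            if a == 0 and b == 0:
                e += params.stacks[(x[i1], x[i2], y[j1], y[j2])]
            else:
                if a > params.max_loop or b > params.max_loop:
                    return math.inf
                e += params.loop_penalty(a, b)
        return e

    def extend(chain):
        nonlocal best
        if chain:
            e = energy(chain)
            if e < best:
                best = e
        last = chain[-1] if chain else (-1, -1)
        for i, j in pairs:
            if i > last[0] and j > last[1]:
                extend(chain + [(i, j)])

    extend([])
    return best


def welch_t_p(a, b):
    """Two-sided Welch t-test from the textbook formula."""
    from scipy import stats

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * stats.t.sf(abs(t), df)
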