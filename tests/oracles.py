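"""Independent brute-force oracles used to validate the DP implementation.

Everything here enumerates explicitly over all 2^N patterns or sums
directly over probability vectors; none of it shares code with the
transfer-matrix path it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def enum_weights(a, b, c, rho, d, d_cap=1000.0):
    """All 2^N patterns and their unnormalized Boltzmann weights."""
    n = len(rho)
    alpha = a + b * np.asarray(rho, dtype=float)
    beta = c / np.minimum(np.asarray(d, dtype=float), d_cap) if n > 1 else np.empty(0)
    patterns = list(itertools.product((0, 1), repeat=n))
    weights = []
    for x in patterns:
        s = [2 * xi - 1 for xi in x]
        energy = sum(alpha[i] * s[i] for i in range(n))
        energy += sum(beta[i] * s[i] * s[i + 1] for i in range(n - 1))
        weights.append(math.exp(energy))
    return patterns, np.array(weights)


def enum_partition(a, b, c, rho, d):
    return enum_weights(a, b, c, rho, d)[1].sum()


def enum_level_distribution(a, b, c, rho, d, subset):
    """P(k methylated among ``subset``) by full enumeration."""
    patterns, weights = enum_weights(a, b, c, rho, d)
    k_total = len(subset)
    mass = np.zeros(k_total + 1)
    for x, w in zip(patterns, weights):
        mass[sum(x[i] for i in subset)] += w
    return mass / mass.sum()


def enum_read_marginal(a, b, c, rho, d, start, calls):
    """P(observed calls) by summing weights of consistent patterns."""
    patterns, weights = enum_weights(a, b, c, rho, d)
    total = weights.sum()
    consistent = 0.0
    for x, w in zip(patterns, weights):
        ok = True
        for m, ch in enumerate(calls):
            if (ch == "M" and x[start + m] != 1) or (ch == "U" and x[start + m] != 0):
                ok = False
                break
        if ok:
            consistent += w
    return consistent / total


def direct_jsd(p, q):
    """Jensen-Shannon distance by direct summation of the two KL terms."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    kl_pm = sum(pi * math.log2(pi / mi) for pi, mi in zip(p, m) if pi > 0)
    kl_qm = sum(qi * math.log2(qi / mi) for qi, mi in zip(q, m) if qi > 0)
    return math.sqrt(max(0.5 * kl_pm + 0.5 * kl_qm, 0.0))


def direct_bh(pvalues):
    """Benjamini-Hochberg step-up by the textbook construction."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adjusted[idx] = running
    return adjusted


def grid_search_a(neg_loglik, grid):
    """1D grid-search oracle over the field intercept a."""
    values = [neg_loglik(a) for a in grid]
    return grid[int(np.argmin(values))]
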