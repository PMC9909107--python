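"""Exact small-n moments of the unfolded SFS by enumerating coalescent
size-configuration trajectories.

For the Kingman coalescent on n leaves, L_k (total branch length
subtending k leaves) satisfies L_k = sum_m c_{m,k} T_m, where the
T_m ~ Exp(m(m-1)/2) epoch durations are independent and c_{m,k} counts
lineages of size k while m lineages remain.  Enumerating all
size-multiset trajectories with their merge probabilities gives exact
E[L_k] and E[L_k L_l], hence exact Cov(xi_i, xi_j) for Poisson mutations
at rate theta/2 per unit length.  Completely independent of the Fu
(1995) closed forms it is used to check.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np


@lru_cache(maxsize=None)
def _trajectories(n: int):
    """All (probability, states) chains from n singletons to one lineage.

    Each state is a sorted tuple of subtree sizes; merge choices are
    weighted by the number of lineage pairs realizing them.
    """
    out = []

    def recurse(state: tuple[int, ...], prob: float, chain: list):
        chain = chain + [state]
        m = len(state)
        if m == 1:
            out.append((prob, chain))
            return
        total_pairs = m * (m - 1) / 2
        from collections import Counter

        counts = Counter(state)
        seen = set()
        for a, b in combinations(sorted(counts), 2):
            ways = counts[a] * counts[b]
            child = tuple(sorted(_merge(state, a, b)))
            recurse(child, prob * ways / total_pairs, chain)
            seen.add((a, b))
        for a in counts:
            if counts[a] >= 2:
                ways = counts[a] * (counts[a] - 1) / 2
                child = tuple(sorted(_merge(state, a, a)))
                recurse(child, prob * ways / total_pairs, chain)

    recurse(tuple([1] * n), 1.0, [])
    return out


def _merge(state, a, b):
    s = list(state)
    s.remove(a)
    s.remove(b)
    s.append(a + b)
    return s


def branch_length_moments(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(E[L_k], E[L_k L_l]) for k, l = 1..n-1 (index 0 == size 1)."""
    EL = np.zeros(n - 1)
    ELL = np.zeros((n - 1, n - 1))
    for prob, chain in _trajectories(n):
        # chain[i] has n - i lineages; epoch with m lineages has
        # E[T] = 1/lam, E[T^2] = 2/lam^2, lam = m(m-1)/2
        states = [s for s in chain if len(s) >= 2]
        c = []  # per epoch: (lam, count-vector over sizes 1..n-1)
        for s in states:
            m = len(s)
            lam = m * (m - 1) / 2.0
            vec = np.zeros(n - 1)
            for size in s:
                if size <= n - 1:
                    vec[size - 1] += 1
            c.append((lam, vec))
        el = np.zeros(n - 1)
        ell = np.zeros((n - 1, n - 1))
        for lam, vec in c:
            el += vec / lam
        for i, (lam_i, vec_i) in enumerate(c):
            for j, (lam_j, vec_j) in enumerate(c):
                if i == j:
                    ell += np.outer(vec_i, vec_i) * (2.0 / lam_i**2)
                else:
                    ell += np.outer(vec_i, vec_j) / (lam_i * lam_j)
        EL += prob * el
        ELL += prob * ell
    return EL, ELL


def sigma_exact(n: int) -> np.ndarray:
    """Exact Fu sigma_ij: Cov(xi_i,xi_j) = delta theta/i + sigma_ij theta^2."""
    EL, ELL = branch_length_moments(n)
    return (ELL - np.outer(EL, EL)) / 4.0


def xi_covariance_exact(n: int, theta: float) -> np.ndarray:
    EL, _ = branch_length_moments(n)
    sig = sigma_exact(n)
    return sig * theta**2 + np.diag(theta / np.arange(1, n))
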