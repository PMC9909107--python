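"""Neutral-coalescent moments of the unfolded site-frequency spectrum.

Under the standard neutral coalescent with scaled mutation rate theta
(per locus), the count xi_i of derived mutations carried by i of n
sampled sequences satisfies

    E[xi_i]        = theta / i
    Cov(xi_i,xi_j) = delta_ij theta / i + sigma_ij theta^2

with the sigma_ij of Fu (1995).  These second moments let any linear
SFS statistic (all the classic neutrality-test numerators) be equipped
with its exact variance, which is how the singleton-excluded Tajima-like
test (Achaz 2008) is built here and how the frozen closed-form constants
of the named tests are cross-checked.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return float(sum(1.0 / i for i in range(1, n)))


def harmonic2(n: int) -> float:
    """b_n = sum_{i=1}^{n-1} 1/i^2."""
    return float(sum(1.0 / (i * i) for i in range(1, n)))


def _beta(n: int, i: int) -> float:
    """Fu (1995) beta_n(i), defined for 1 <= i <= n - 1... (i can reach n
    in the formulas below via beta_n(j+1); the closed form still holds)."""
    an1 = harmonic(n + 1)  # sum_{k=1}^{n} 1/k
    ai = harmonic(i)       # sum_{k=1}^{i-1} 1/k
    return 2.0 * n * (an1 - ai) / ((n - i + 1) * (n - i)) - 2.0 / (n - i)


@lru_cache(maxsize=None)
def sigma_matrix(n: int) -> np.ndarray:
    """(n-1) x (n-1) matrix of Fu (1995) sigma_ij, index 0 == frequency 1."""
    if n < 2:
        raise ValueError("need n >= 2")
    an = harmonic(n)
    sig = np.zeros((n - 1, n - 1))
    for i in range(1, n):
        if 2 * i < n:
            sig[i - 1, i - 1] = _beta(n, i + 1)
        elif 2 * i == n:
            sig[i - 1, i - 1] = 2.0 * (an - harmonic(i)) / (n - i) - 1.0 / (i * i)
        else:
            sig[i - 1, i - 1] = _beta(n, i) - 1.0 / (i * i)
    for i in range(1, n):
        for j in range(1, i):
            # i > j
            if i + j < n:
                val = (_beta(n, i + 1) - _beta(n, i)) / 2.0
            elif i + j == n:
                val = (
                    (an - harmonic(i)) / (n - i)
                    + (an - harmonic(j)) / (n - j)
                    - (_beta(n, i) + _beta(n, j + 1)) / 2.0
                    - 1.0 / (i * j)
                )
            else:
                val = (_beta(n, j) - _beta(n, j + 1)) / 2.0 - 1.0 / (i * j)
            sig[i - 1, j - 1] = sig[j - 1, i - 1] = val
    return sig


def numerator_variance_coefficients(
    n: int, weights: np.ndarray
) -> tuple[float, float]:
    """(alpha, beta) with Var(sum_i w_i xi_i) = alpha theta + beta theta^2."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (n - 1,):
        raise ValueError(f"weights must have length n-1 = {n - 1}")
    i = np.arange(1, n)
    alpha = float(np.sum(w * w / i))
    beta = float(w @ sigma_matrix(n) @ w)
    return alpha, beta


# ---------------------------------------------------------------------------
# canonical estimator weight vectors (theta-unbiased: sum_i w_i / i = 1)
# ---------------------------------------------------------------------------


def weights_theta_pi(n: int) -> np.ndarray:
    i = np.arange(1, n)
    return 2.0 * i * (n - i) / (n * (n - 1.0))


def weights_theta_w(n: int) -> np.ndarray:
    return np.full(n - 1, 1.0 / harmonic(n))


def weights_theta_l(n: int) -> np.ndarray:
    return np.arange(1, n) / (n - 1.0)


def weights_theta_h(n: int) -> np.ndarray:
    i = np.arange(1, n)
    return 2.0 * i * i / (n * (n - 1.0))
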