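"""Frequency-spectrum neutrality tests.

Implements the classic battery: Tajima's D; Fu & Li's D*, F* (folded,
singleton-based) and D, F (outgroup-polarized); the normalized Fay & Wu
H; Zeng's E; and the singleton-excluded Tajima-like Y statistic of
Achaz.  All statistics share one construction: an SFS-linear numerator
with zero expectation under neutrality, divided by the square root of an
unbiased estimate of its variance.  The variance coefficients
(Var = alpha theta + beta theta^2) are generated in one place
(:func:`test_constants`) directly from the exact second moments of the
spectrum (Fu 1995) and therefore agree with the corrected published
constant sets used by mainstream software (DnaSP conventions):

* Tajima-style plug-in uses S and S(S-1) (Tajima 1989 e1/e2);
* Fu & Li tests plug eta and eta^2 (Fu & Li 1993 u/v, with the
  variance-constant corrections of Simonsen et al. 1995);
* H and E plug theta_W and the S(S-1) estimator of theta^2
  (Zeng et al. 2006).

Undefined statistics propagate as NaN with a reason, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from .popstats import PolymorphismTable, UnfoldedSFS
from .sfs import (
    harmonic,
    harmonic2,
    numerator_variance_coefficients,
    weights_theta_l,
    weights_theta_pi,
    weights_theta_w,
)

POLARIZED_STATS = ("fay_wu_h_norm", "zeng_e", "fu_li_d", "fu_li_f")
FOLDED_STATS = ("tajima_d", "fu_li_d_star", "fu_li_f_star", "achaz_y")


@dataclass(frozen=True)
class NeutralityConstants:
    """Tajima (1989) constants for sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@lru_cache(maxsize=None)
def neutrality_constants(n: int) -> NeutralityConstants:
    if n < 2:
        raise ValueError("need n >= 2")
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    return NeutralityConstants(
        n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2,
        e1=c1 / a1, e2=c2 / (a1 * a1 + a2),
    )


def _numerator_weights(name: str, n: int) -> np.ndarray:
    """Unfolded-SFS weight vector of each statistic's numerator."""
    i = np.arange(1, n)
    w_pi = weights_theta_pi(n)
    w_w = weights_theta_w(n)
    w_l = weights_theta_l(n)
    a1 = harmonic(n)
    if name == "tajima_d":
        return w_pi - 1.0 / a1          # pi_total - S/a1
    if name == "fu_li_d":
        w = np.ones(n - 1)
        w[0] -= a1                      # eta - a1 * xi_1
        return w
    if name == "fu_li_f":
        w = w_pi.copy()
        w[0] -= 1.0                     # pi_total - xi_1
        return w
    if name == "fu_li_d_star":
        w = np.full(n - 1, n / (n - 1.0))
        w[0] -= a1                      # folded singletons: xi_1 + xi_{n-1}
        w[-1] -= a1
        return w
    if name == "fu_li_f_star":
        w = w_pi.copy()
        w[0] -= (n - 1.0) / n
        w[-1] -= (n - 1.0) / n
        return w
    if name == "fay_wu_h_norm":
        return w_pi - w_l               # theta_pi - theta_L
    if name == "zeng_e":
        return w_l - w_w                # theta_L - theta_W
    if name == "achaz_y":
        keep = (i >= 2) & (i <= n - 2)
        wp = i * (n - i) * keep.astype(float)
        wp /= np.sum(wp / i)
        a_prime = a1 - 1.0 - 1.0 / (n - 1)
        ww = keep.astype(float) / a_prime
        return wp - ww
    raise ValueError(f"unknown statistic {name!r}")


@lru_cache(maxsize=None)
def test_constants(name: str, n: int) -> tuple[float, float]:
    """(alpha, beta) with Var(numerator) = alpha theta + beta theta^2."""
    return numerator_variance_coefficients(n, _numerator_weights(name, n))


def _plug_in_s(name: str, n: int, S: float) -> float:
    """Denominator^2 from S and S(S-1) (Tajima/Zeng convention)."""
    alpha, beta = test_constants(name, n)
    a1, a2 = harmonic(n), harmonic2(n)
    return alpha * S / a1 + beta * S * (S - 1) / (a1 * a1 + a2)


def _plug_in_eta(name: str, n: int, eta: float) -> float:
    """Denominator^2 from eta and eta^2 (Fu & Li convention)."""
    alpha, beta = test_constants(name, n)
    a1, a2 = harmonic(n), harmonic2(n)
    v = beta / (a1 * a1 + a2)
    u = alpha / a1 - v
    return u * eta + v * eta * eta


# ---------------------------------------------------------------------------
# the statistics
# ---------------------------------------------------------------------------


def tajima_d(S: int, pi_total: float, n: int) -> float:
    """Tajima's D from segregating sites and mean pairwise differences.

    ``pi_total`` is the mean pairwise difference *count* (k-hat), not a
    per-site value.  Undefined (NaN) when S == 0 or n < 4.
    """
    if n < 4 or S == 0:
        return math.nan
    c = neutrality_constants(n)
    denom = math.sqrt(c.e1 * S + c.e2 * S * (S - 1))
    return (pi_total - S / c.a1) / denom


def fu_li_star(S: int, eta: int, eta_singletons: int, pi_total: float, n: int
               ) -> tuple[float, float]:
    """Fu & Li's D* and F* (no outgroup; singletons folded)."""
    if n < 4 or eta == 0:
        return math.nan, math.nan
    a1 = harmonic(n)
    num_d = (n / (n - 1.0)) * eta - a1 * eta_singletons
    d_star = num_d / math.sqrt(_plug_in_eta("fu_li_d_star", n, eta))
    num_f = pi_total - ((n - 1.0) / n) * eta_singletons
    f_star = num_f / math.sqrt(_plug_in_eta("fu_li_f_star", n, eta))
    return d_star, f_star


def fu_li_outgroup(eta: int, eta_ext: int, pi_total: float, n: int
                   ) -> tuple[float, float]:
    """Fu & Li's D and F using derived singletons (external mutations)."""
    if n < 4 or eta == 0:
        return math.nan, math.nan
    a1 = harmonic(n)
    d = (eta - a1 * eta_ext) / math.sqrt(_plug_in_eta("fu_li_d", n, eta))
    f = (pi_total - eta_ext) / math.sqrt(_plug_in_eta("fu_li_f", n, eta))
    return d, f


def theta_pi_from_sfs(sfs: UnfoldedSFS) -> float:
    return float(weights_theta_pi(sfs.n) @ sfs.xi[1:])


def theta_h_from_sfs(sfs: UnfoldedSFS) -> float:
    n = sfs.n
    i = np.arange(1, n)
    return float(np.sum(2.0 * i * i * sfs.xi[1:] / (n * (n - 1.0))))


def theta_l_from_sfs(sfs: UnfoldedSFS) -> float:
    return float(weights_theta_l(sfs.n) @ sfs.xi[1:])


def fay_wu_h_norm(sfs: UnfoldedSFS) -> float:
    """Normalized Fay & Wu H (Zeng et al. 2006): (theta_pi - theta_L) over
    its estimated standard deviation."""
    S = sfs.segregating
    if S == 0 or sfs.n < 4:
        return math.nan
    num = theta_pi_from_sfs(sfs) - theta_l_from_sfs(sfs)
    return num / math.sqrt(_plug_in_s("fay_wu_h_norm", sfs.n, S))


def zeng_e(sfs: UnfoldedSFS) -> float:
    """Zeng et al. (2006) E: (theta_L - theta_W) over its estimated SD."""
    S = sfs.segregating
    if S == 0 or sfs.n < 4:
        return math.nan
    a1 = harmonic(sfs.n)
    num = theta_l_from_sfs(sfs) - S / a1
    return num / math.sqrt(_plug_in_s("zeng_e", sfs.n, S))


def achaz_y(table: PolymorphismTable, n: int | None = None) -> float:
    """Tajima-like Y computed after removing singletons (Achaz 2008).

    Works on the folded spectrum of minor-allele counts; multiallelic
    sites contribute each non-major allele as one variant.
    """
    n = n or table.n
    if n < 4:
        return math.nan
    folded = np.zeros(n // 2 + 1, dtype=np.int64)
    for site in table.sites:
        counts = sorted(site.alleles.values(), reverse=True)
        for minor in counts[1:]:
            folded[min(minor, n - minor)] += 1
    S_prime = int(folded[2:].sum())
    if S_prime == 0:
        return math.nan
    w = _numerator_weights("achaz_y", n)
    # w is symmetric (w_i == w_{n-i}), so summing w_i over folded minor
    # classes equals the unfolded sum: each folded bin already aggregates
    # the two mirrored unfolded frequencies
    num = 0.0
    for i in range(2, n // 2 + 1):
        num += w[i - 1] * folded[i]
    alpha, beta = test_constants("achaz_y", n)
    a_prime = harmonic(n) - 1.0 - 1.0 / (n - 1)
    keep = np.zeros(n - 1)
    keep[1 : n - 2] = 1.0
    _, b_prime = numerator_variance_coefficients(n, keep)
    theta_hat = S_prime / a_prime
    theta2_hat = S_prime * (S_prime - 1) / (a_prime**2 + b_prime)
    denom2 = alpha * theta_hat + beta * theta2_hat
    return num / math.sqrt(denom2)


# ---------------------------------------------------------------------------
# suite + significance
# ---------------------------------------------------------------------------


@dataclass
class NeutralitySuiteResult:
    site_class: str
    n: int
    S: int
    eta: int
    tajima_d: float
    fu_li_d_star: float
    fu_li_f_star: float
    achaz_y: float
    fu_li_d: float = math.nan
    fu_li_f: float = math.nan
    fay_wu_h_norm: float = math.nan
    zeng_e: float = math.nan
    undefined_reason: str | None = None


def neutrality_suite(summary, site_class: str = "all",
                     sfs: UnfoldedSFS | None = None) -> NeutralitySuiteResult:
    """All tests on one :class:`~gadpopgen.popstats.AlignmentSummary`.

    Outgroup-polarized statistics (H, E, Fu-Li D/F) are filled only when
    an unfolded SFS is supplied and the class is 'all' (polarization is
    site-class-agnostic here).
    """
    n = summary.n
    table = summary.table
    S = summary.S_class(site_class)
    eta = table.eta_count(site_class)
    pi_total = summary.pi_total(site_class)
    reason = None
    if n < 4:
        reason = "n < 4"
    elif S == 0:
        reason = "no segregating sites"
    d_star, f_star = fu_li_star(S, eta, table.singletons(site_class), pi_total, n)
    result = NeutralitySuiteResult(
        site_class=site_class,
        n=n,
        S=S,
        eta=eta,
        tajima_d=tajima_d(S, pi_total, n),
        fu_li_d_star=d_star,
        fu_li_f_star=f_star,
        achaz_y=achaz_y(table, n) if site_class == "all" else math.nan,
        undefined_reason=reason,
    )
    if sfs is not None and site_class == "all":
        result.fay_wu_h_norm = fay_wu_h_norm(sfs)
        result.zeng_e = zeng_e(sfs)
        eta_ext = int(sfs.xi[1])
        d, f = fu_li_outgroup(sfs.segregating, eta_ext,
                              float(weights_theta_pi(n) @ sfs.xi[1:]), n)
        result.fu_li_d = d
        result.fu_li_f = f
    return result


# -- null simulation --------------------------------------------------------


def sample_branch_length_classes(n: int, reps: int, rng: np.random.Generator
                                 ) -> np.ndarray:
    """Total branch length subtending k leaves (k = 1..n-1) for ``reps``
    independent Kingman genealogies; shape (reps, n-1)."""
    L = np.zeros((reps, n - 1))
    sizes = np.ones((reps, n), dtype=np.int64)
    rows = np.arange(reps)
    for m in range(n, 1, -1):
        lam = m * (m - 1) / 2.0
        t = rng.exponential(1.0 / lam, reps)
        np.add.at(
            L,
            (np.repeat(rows, m), (sizes[:, :m] - 1).ravel()),
            np.repeat(t, m),
        )
        i = rng.integers(0, m, reps)
        j = rng.integers(0, m - 1, reps)
        j = j + (j >= i)
        sizes[rows, i] += sizes[rows, j]
        sizes[rows, j] = sizes[rows, m - 1]
    return L


def sample_sfs_fixed_s(n: int, S: int, reps: int, rng: np.random.Generator
                       ) -> np.ndarray:
    """Neutral unfolded SFS replicates conditioned on S segregating sites."""
    L = sample_branch_length_classes(n, reps, rng)
    p = L / L.sum(axis=1, keepdims=True)
    return rng.multinomial(S, p)


def sample_sfs_theta(n: int, theta: float, reps: int, rng: np.random.Generator
                     ) -> np.ndarray:
    """Neutral unfolded SFS replicates at fixed theta (per locus)."""
    L = sample_branch_length_classes(n, reps, rng)
    return rng.poisson(theta / 2.0 * L)


def statistic_from_sfs_matrix(name: str, xi: np.ndarray, n: int) -> np.ndarray:
    """Vectorized statistic over SFS replicates (rows of ``xi``)."""
    xi = np.asarray(xi, dtype=float)
    S = xi.sum(axis=1)
    a1, a2 = harmonic(n), harmonic2(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        if name == "tajima_d":
            c = neutrality_constants(n)
            num = xi @ weights_theta_pi(n) - S / a1
            den = np.sqrt(c.e1 * S + c.e2 * S * (S - 1))
            return np.where(S > 0, num / den, np.nan)
        if name in ("fay_wu_h_norm", "zeng_e"):
            w = _numerator_weights(name, n)
            alpha, beta = test_constants(name, n)
            num = xi @ w
            den2 = alpha * S / a1 + beta * S * (S - 1) / (a1 * a1 + a2)
            return np.where(S > 0, num / np.sqrt(den2), np.nan)
        if name in ("fu_li_d", "fu_li_f", "fu_li_d_star", "fu_li_f_star"):
            w = _numerator_weights(name, n)
            alpha, beta = test_constants(name, n)
            v = beta / (a1 * a1 + a2)
            u = alpha / a1 - v
            num = xi @ w
            den2 = u * S + v * S * S
            return np.where(S > 0, num / np.sqrt(den2), np.nan)
        if name == "achaz_y":
            w = _numerator_weights(name, n)
            keep = np.zeros(n - 1)
            keep[1 : n - 2] = 1.0
            a_prime = a1 - 1.0 - 1.0 / (n - 1)
            _, b_prime = numerator_variance_coefficients(n, keep)
            alpha, beta = test_constants(name, n)
            Sp = xi @ keep
            num = xi @ w
            den2 = alpha * Sp / a_prime + beta * Sp * (Sp - 1) / (
                a_prime**2 + b_prime
            )
            return np.where(Sp > 0, num / np.sqrt(den2), np.nan)
    raise ValueError(f"unknown statistic {name!r}")


def test_significance(
    stat: str,
    value: float,
    n: int,
    S: int,
    method: str = "coalescent_null",
    reps: int = 5000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-tailed p-value for an observed statistic.

    ``beta_approx`` is Tajima's (1989) beta approximation (Tajima's D
    only).  ``coalescent_null`` simulates neutral replicates conditioned
    on n and the observed S (fixed-S) and doubles the smaller empirical
    tail, capped at 1.
    """
    if math.isnan(value):
        return math.nan
    if method == "beta_approx":
        if stat != "tajima_d":
            raise ValueError("beta_approx is defined for Tajima's D only")
        c = neutrality_constants(n)
        dmin = (2.0 / n - 1.0 / c.a1) / math.sqrt(c.e2)
        dmax = ((n + 1.0) / (2.0 * n) - 1.0 / c.a1) / math.sqrt(c.e2)
        # Beta on [dmin, dmax] with mean 0, variance 1 (Tajima 1989)
        rng_w = dmax - dmin
        alpha = -(1.0 + dmin * dmax) * dmax / rng_w
        beta_p = (1.0 + dmin * dmax) * dmin / rng_w
        x = (value - dmin) / rng_w
        x = min(max(x, 0.0), 1.0)
        cdf = sps.beta.cdf(x, beta_p, alpha)
        return min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    if method == "coalescent_null":
        if reps < 1000:
            raise ValueError("coalescent_null needs reps >= 1000")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        xi = sample_sfs_fixed_s(n, S, reps, rng)
        null = statistic_from_sfs_matrix(stat, xi, n)
        null = null[~np.isnan(null)]
        lo = (np.sum(null <= value) + 1.0) / (null.size + 1.0)
        hi = (np.sum(null >= value) + 1.0) / (null.size + 1.0)
        return min(1.0, 2.0 * min(lo, hi))
    raise ValueError(f"unknown method {method!r}")


def significance_stars(p: float) -> str:
    """DnaSP-style marks: # for 0.05<p<0.10, then * / ** / ***."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "#"
    return ""
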