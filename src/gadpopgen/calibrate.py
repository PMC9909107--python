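"""Simulation-based calibration and recovery experiments.

These routines run the full analysis stack on synthetic data from
:mod:`~gadpopgen.coalsim` and summarize how well the estimators and
tests behave under known conditions: neutral means of the test battery,
Watterson/pi parameter recovery, type-I error of fixed-S significance,
and the direction-of-selection recovery of the MK machinery.  They are
shared by the test suite and the reproduction script.
"""

from __future__ import annotations

import math

import numpy as np

from . import mkdivergence, neutrality, popstats
from .coalsim import CoalescentParams, simulate
from .popstats import AlignmentSummary
from .sfs import harmonic

STAT_NAMES = (
    "tajima_d", "fu_li_d_star", "fu_li_f_star", "fu_li_d", "fu_li_f",
    "fay_wu_h_norm", "zeng_e", "achaz_y",
)


def neutral_calibration(
    n: int = 20,
    theta: float = 5.0,
    L_codons: int = 500,
    reps: int = 2000,
    t_div: float = 2.0,
    seed: int = 0,
) -> dict[str, float]:
    """Means of the neutrality statistics and diversity estimators over
    neutral replicates (full sequence pipeline, outgroup-polarized)."""
    rng = np.random.default_rng(seed)
    params = CoalescentParams(n=n, theta=theta, L_codons=L_codons, t_div=t_div)
    sums = {name: [] for name in STAT_NAMES}
    S_list, pi_list, thetaw_list = [], [], []
    for _ in range(reps):
        res = simulate(params, rng=rng)
        summary = AlignmentSummary(res.alignment)
        sfs = popstats.polarize(res.alignment)
        suite = neutrality.neutrality_suite(summary, "all", sfs=sfs)
        for name in STAT_NAMES:
            sums[name].append(getattr(suite, name))
        S_list.append(summary.table.S)
        pi_list.append(summary.pi_total("all"))
        thetaw_list.append(summary.table.S / harmonic(n))
    out = {f"mean_{k}": float(np.nanmean(v)) for k, v in sums.items()}
    out.update(
        mean_S=float(np.mean(S_list)),
        se_S=float(np.std(S_list) / math.sqrt(reps)),
        expected_S=theta * harmonic(n),
        mean_pi_per_gene=float(np.mean(pi_list)),
        se_pi=float(np.std(pi_list) / math.sqrt(reps)),
        mean_theta_w_per_gene=float(np.mean(thetaw_list)),
        se_theta_w=float(np.std(thetaw_list) / math.sqrt(reps)),
        theta_true=theta,
        reps=reps,
    )
    return out


def rejection_rate(
    n: int = 20,
    theta: float = 5.0,
    trials: int = 10_000,
    level: float = 0.05,
    null_reps: int = 2000,
    seed: int = 0,
    stat: str = "tajima_d",
) -> float:
    """Empirical type-I error of the fixed-S coalescent-null test at a
    nominal level, over neutral SFS trials.

    Null distributions are cached per observed S, so the experiment
    costs O(distinct S) null batches rather than O(trials).
    """
    rng = np.random.default_rng(seed)
    xi = neutrality.sample_sfs_theta(n, theta, trials, rng)
    obs = neutrality.statistic_from_sfs_matrix(stat, xi, n)
    S_obs = xi.sum(axis=1)
    null_cache: dict[int, np.ndarray] = {}
    rejected = 0
    valid = 0
    for value, S in zip(obs, S_obs):
        if np.isnan(value) or S == 0:
            continue
        S = int(S)
        if S not in null_cache:
            null_xi = neutrality.sample_sfs_fixed_s(n, S, null_reps, rng)
            null = neutrality.statistic_from_sfs_matrix(stat, null_xi, n)
            null_cache[S] = np.sort(null[~np.isnan(null)])
        null = null_cache[S]
        lo = (np.searchsorted(null, value, side="right") + 1.0) / (null.size + 1.0)
        hi = (null.size - np.searchsorted(null, value, side="left") + 1.0) / (
            null.size + 1.0
        )
        p = min(1.0, 2.0 * min(lo, hi))
        valid += 1
        rejected += p < level
    return rejected / valid


def pi_ratio_recovery(
    reps: int = 200,
    n: int = 20,
    theta: float = 5.0,
    L_codons: int = 500,
    f_constrained: float = 0.2,
    seed: int = 0,
) -> float:
    """Fraction of paired replicates in which pi_N/pi_S under purifying
    acceptance ``f_constrained`` falls below the neutral (f = 1) value.

    Pairs share the replicate seed, so the genealogies are common random
    numbers and the comparison isolates the acceptance effect.
    """
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=reps)
    wins = used = 0
    for s in base:
        ratios = []
        for f in (f_constrained, 1.0):
            res = simulate(
                CoalescentParams(
                    n=n, theta=theta, L_codons=L_codons, f_poly=f, seed=int(s)
                )
            )
            summary = AlignmentSummary(res.alignment)
            pi_n = summary.pi_raw("nonsyn")
            pi_s = summary.pi_raw("syn")
            ratios.append(pi_n / pi_s if pi_s > 0 else math.nan)
        if any(math.isnan(r) for r in ratios):
            continue
        used += 1
        wins += ratios[0] < ratios[1]
    if used == 0:
        raise RuntimeError("no informative pairs")
    return wins / used


def dos_recovery(
    reps: int = 500,
    n: int = 20,
    theta: float = 5.0,
    L_codons: int = 500,
    f_poly: float = 0.2,
    f_div: float = 0.8,
    t_div: float = 3.0,
    seed: int = 0,
) -> float:
    """Mean DoS over replicates with distinct polymorphism/divergence
    acceptance of nonsynonymous changes (positive when f_div > f_poly)."""
    rng = np.random.default_rng(seed)
    params = CoalescentParams(
        n=n, theta=theta, L_codons=L_codons, f_poly=f_poly, f_div=f_div,
        t_div=t_div,
    )
    values = []
    for _ in range(reps):
        res = simulate(params, rng=rng)
        aln = res.alignment
        comp = aln.outgroup
        ingroup_only = type(aln)(
            records=aln.ingroup, populations={}, outgroup_id=None,
            table_id=aln.table_id,
        )
        tbl = mkdivergence.mk_test(mkdivergence.mk_counts(ingroup_only, comp))
        if not math.isnan(tbl.DoS):
            values.append(tbl.DoS)
    return float(np.mean(values))
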