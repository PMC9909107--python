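"""Codon-structured neutral coalescent simulator.

Generates population-structured samples of aligned coding sequences with
the statistical features the analysis stack is built to detect:
controllable theta, rare-variant excess (exponential growth), purifying
selection against amino-acid changes (acceptance thinning of
nonsynonymous mutations at probability ``f_poly``), and an outgroup at
controllable divergence whose nonsynonymous acceptance ``f_div`` can be
raised above ``f_poly`` to mimic adaptive protein divergence.

Selection is emulated by mutation-acceptance thinning on a neutral
genealogy rather than by a diffusion model: it is cheap, reproducible,
and gives exactly the reduced-pi_N / MK-asymmetry structure the tests
measure, with known ground truth.  Mutations follow the infinite-sites
convention (each nucleotide position hit at most once; saturation is an
error), and mutation type is classified against the root codon context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codons import DEFAULT_TABLE_ID, codon_map, sense_codons
from .seqio import CodingAlignment, SequenceRecord, write_fasta

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class CoalescentParams:
    n: int = 20
    theta: float = 5.0            # per gene
    L_codons: int = 500
    growth: float = 0.0           # exponential growth rate, 0 = constant size
    f_poly: float = 1.0           # acceptance of nonsynonymous mutations (ingroup)
    f_div: float = 1.0            # acceptance on the outgroup branch
    t_div: float = 0.0            # outgroup branch length, coalescent units; 0 = none
    pops: int = 1
    seed: int = 0
    table_id: int = DEFAULT_TABLE_ID

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n >= 2 required")
        if self.theta < 0:
            raise ValueError("theta >= 0 required")
        if self.L_codons < 1:
            raise ValueError("L_codons >= 1 required")
        for f in (self.f_poly, self.f_div):
            if not 0.0 <= f <= 1.0:
                raise ValueError("acceptance fractions must be in [0, 1]")


@dataclass(frozen=True)
class Mutation:
    position: int        # nt position
    ancestral: str
    derived: str
    synonymous: bool
    n_carriers: int      # ingroup leaves carrying the derived allele
    on_outgroup: bool = False


@dataclass
class SimulationResult:
    alignment: CodingAlignment
    mutations: list[Mutation]
    tree_total_length: float
    params: CoalescentParams

    @property
    def true_sfs(self) -> np.ndarray:
        """Derived-allele frequency spectrum of the ingroup mutations."""
        xi = np.zeros(self.params.n, dtype=np.int64)
        for m in self.mutations:
            if not m.on_outgroup and 0 < m.n_carriers < self.params.n:
                xi[m.n_carriers] += 1
        return xi

    def write(self, outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        """FASTA + population TSV + truth JSON, so the whole pipeline can
        run on synthetic data unchanged."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / f"{prefix}.fasta"
        write_fasta(list(self.alignment.records), fasta)
        popmap = outdir / f"{prefix}.populations.tsv"
        with open(popmap, "w") as fh:
            for rid, pop in self.alignment.populations.items():
                fh.write(f"{rid}\t{pop}\n")
        truth = outdir / f"{prefix}.truth.json"
        with open(truth, "w") as fh:
            json.dump(
                {
                    "params": {
                        k: getattr(self.params, k)
                        for k in (
                            "n", "theta", "L_codons", "growth", "f_poly",
                            "f_div", "t_div", "pops", "seed",
                        )
                    },
                    "tree_total_length": self.tree_total_length,
                    "mutations": [
                        {
                            "position": m.position,
                            "ancestral": m.ancestral,
                            "derived": m.derived,
                            "synonymous": m.synonymous,
                            "n_carriers": m.n_carriers,
                            "on_outgroup": m.on_outgroup,
                        }
                        for m in self.mutations
                    ],
                },
                fh,
                indent=1,
            )
        return {"fasta": fasta, "populations": popmap, "truth": truth}


# ---------------------------------------------------------------------------


def _sample_genealogy(n: int, growth: float, rng: np.random.Generator):
    """Kingman genealogy; returns per-branch (leaf-set, length).

    Under exponential growth g the pairwise coalescence intensity at
    time t back is e^{g t}; waiting times are obtained by inverting the
    cumulative intensity of the constant-size exponential draw.
    """
    lineages: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    birth = {fs: 0.0 for fs in lineages}  # time each lineage appeared
    branches: list[tuple[frozenset[int], float]] = []
    t = 0.0
    while len(lineages) > 1:
        m = len(lineages)
        lam = m * (m - 1) / 2.0
        e = rng.exponential(1.0)
        if growth == 0.0:
            wait = e / lam
        else:
            wait = np.log(np.exp(growth * t) + growth * e / lam) / growth - t
        t += wait
        i, j = sorted(rng.choice(m, size=2, replace=False))
        a, b = lineages[j], lineages[i]
        for fs in (a, b):
            branches.append((fs, t - birth[fs]))
        merged = a | b
        lineages[i] = merged
        del lineages[j]
        birth[merged] = t
    return branches, t


def _random_cds(L_codons: int, table_id: int, rng: np.random.Generator) -> str:
    codons = sense_codons(table_id)
    idx = rng.integers(0, len(codons), L_codons)
    return "".join(codons[i] for i in idx)


def _draw_mutation(
    root: str,
    used: set[int],
    accept_nonsyn: float,
    table_id: int,
    rng: np.random.Generator,
) -> tuple[int, str, str, bool]:
    """One accepted infinite-sites mutation against the root context.

    At most one mutation per *codon*: lineages then stay stop-free and
    every mutation's class is exact in any sequence context.
    """
    cmap = codon_map(table_id)
    L = len(root)
    for _ in range(_MAX_REDRAWS):
        pos = int(rng.integers(0, L))
        if pos // 3 in used:
            continue
        anc = root[pos]
        derived = "ACGT".replace(anc, "")[int(rng.integers(0, 3))]
        cstart = pos - pos % 3
        codon = root[cstart : cstart + 3]
        alt = codon[: pos % 3] + derived + codon[pos % 3 + 1 :]
        if cmap[alt] == "*":
            continue
        synonymous = cmap[alt] == cmap[codon]
        if not synonymous and rng.random() >= accept_nonsyn:
            continue
        used.add(pos // 3)
        return pos, anc, derived, synonymous
    raise RuntimeError(
        "mutation saturation: could not place a mutation after "
        f"{_MAX_REDRAWS} redraws (requested mutations exceed available sites?)"
    )


def simulate(params: CoalescentParams,
             rng: np.random.Generator | None = None) -> SimulationResult:
    """Simulate one gene: ingroup alignment (+ outgroup if t_div > 0)."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    return _simulate(params, rng, star_fraction=0.0)


def simulate_skewed_sfs(params: CoalescentParams, mode: str,
                        rng: np.random.Generator | None = None
                        ) -> SimulationResult:
    """Frequency-spectrum-skewed data.

    ``growth`` uses the params' (positive) growth rate to produce the
    rare-variant excess of expanding or purifying-selection-like
    populations; ``sweep_like`` grafts a star-like subtree so mutations
    above it segregate at high derived frequency (negative H_n).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if mode == "growth":
        return _simulate(params, rng, star_fraction=0.0)
    if mode == "sweep_like":
        return _simulate(params, rng, star_fraction=0.9)
    raise ValueError(f"unknown mode {mode!r}")


def _simulate(params: CoalescentParams, rng: np.random.Generator,
              star_fraction: float) -> SimulationResult:
    n, table_id = params.n, params.table_id
    if star_fraction > 0.0:
        branches, height = _star_genealogy(n, star_fraction, rng)
    else:
        branches, height = _sample_genealogy(n, params.growth, rng)
    total_len = sum(length for _, length in branches)
    root = _random_cds(params.L_codons, table_id, rng)
    L = len(root)
    n_mut = rng.poisson(params.theta / 2.0 * total_len)
    if n_mut > 0.5 * params.L_codons:
        raise RuntimeError(
            f"mutation saturation: {n_mut} mutations requested on "
            f"{params.L_codons} codons (one hit per codon allowed)"
        )
    lengths = np.array([length for _, length in branches])
    branch_of = rng.choice(len(branches), size=n_mut, p=lengths / total_len)
    used: set[int] = set()
    mutations: list[Mutation] = []
    seqs = {i: dict() for i in range(n)}  # leaf -> {pos: derived}
    for b in branch_of:
        leafset, _ = branches[b]
        pos, anc, derived, syn = _draw_mutation(
            root, used, params.f_poly, table_id, rng
        )
        mutations.append(
            Mutation(pos, anc, derived, syn, n_carriers=len(leafset))
        )
        for leaf in leafset:
            seqs[leaf][pos] = derived

    records = []
    width = len(str(n))
    for leaf in range(n):
        s = list(root)
        for pos, derived in seqs[leaf].items():
            s[pos] = derived
        records.append(SequenceRecord(f"seq{leaf:0{width}d}", "".join(s), "nt"))

    outgroup_id = None
    if params.t_div > 0.0:
        n_div = rng.poisson(params.theta / 2.0 * params.t_div)
        if n_div > 0.3 * params.L_codons:
            raise RuntimeError("mutation saturation on the outgroup branch")
        og = list(root)
        for _ in range(n_div):
            pos, anc, derived, syn = _draw_mutation(
                root, used, params.f_div, table_id, rng
            )
            mutations.append(
                Mutation(pos, anc, derived, syn, n_carriers=0, on_outgroup=True)
            )
            og[pos] = derived
        outgroup_id = "outgroup"
        records.append(SequenceRecord(outgroup_id, "".join(og), "nt"))

    pop_labels = [f"pop{k + 1}" for k in range(max(1, params.pops))]
    populations = {
        rec.id: pop_labels[i % len(pop_labels)]
        for i, rec in enumerate(records)
        if rec.id != outgroup_id
    }
    aln = CodingAlignment(
        records=tuple(records),
        populations=populations,
        outgroup_id=outgroup_id,
        table_id=table_id,
    )
    return SimulationResult(
        alignment=aln,
        mutations=mutations,
        tree_total_length=float(total_len),
        params=params,
    )


def _star_genealogy(n: int, star_fraction: float, rng: np.random.Generator):
    """Post-sweep-like genealogy: most leaves coalesce star-like at a
    recent time; the surviving ancestral lineage plus the escapees then
    coalesce normally.  Mutations on the branch above the star subtend
    n - k leaves at high frequency."""
    k_escape = max(1, int(round((1.0 - star_fraction) * n)) - 1) + 1
    swept = list(range(n - k_escape + 1))
    t_star = 0.05
    branches = [(frozenset([i]), t_star) for i in swept]
    # remaining lineages: the star ancestor + escapees, standard coalescent
    lineages = [frozenset(swept)] + [frozenset([i]) for i in range(n - k_escape + 1, n)]
    birth = {fs: t_star for fs in lineages}
    # escapee external branches started at 0
    for fs in lineages[1:]:
        birth[fs] = 0.0
    t = t_star
    while len(lineages) > 1:
        m = len(lineages)
        lam = m * (m - 1) / 2.0
        t += rng.exponential(1.0 / lam)
        i, j = sorted(rng.choice(m, size=2, replace=False))
        a, b = lineages[j], lineages[i]
        for fs in (a, b):
            branches.append((fs, t - birth[fs]))
        merged = a | b
        lineages[i] = merged
        del lineages[j]
        birth[merged] = t
    return branches, t
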