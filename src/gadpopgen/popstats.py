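"""Site classification and nucleotide-diversity estimation.

The engine decomposes every pairwise sequence comparison into per-site,
per-class (synonymous / nonsynonymous) difference contributions using
Nei–Gojobori pathway averaging.  Because both the fractional site counts
and the difference counts are attributed to individual nucleotide
positions, global, per-region and sliding-window statistics are all
exactly additive over codon columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd

from .codons import codon_map, codon_site_fractions, pathway_profile
from .seqio import CodingAlignment

SITE_CLASSES = ("all", "syn", "nonsyn", "silent")


class InternalStopError(ValueError):
    pass


@dataclass(frozen=True)
class SiteClassCounts:
    L_total: float
    L_syn: float
    L_nonsyn: float

    @property
    def L_silent(self) -> float:
        # pure-CDS input: silent sites are the synonymous sites
        return self.L_syn

    def for_class(self, site_class: str) -> float:
        return {
            "all": self.L_total,
            "syn": self.L_syn,
            "nonsyn": self.L_nonsyn,
            "silent": self.L_silent,
        }[site_class]


@dataclass(frozen=True)
class PolymorphicSite:
    """One variable ingroup column of the alignment."""

    position: int              # 0-based nt column
    codon_index: int
    alleles: dict[str, int]    # nucleotide -> ingroup count
    syn_fraction: float        # pathway-averaged synonymous fraction
    site_class: str            # 'synonymous' | 'nonsynonymous'
    singleton: bool
    parsimony_informative: bool
    n_mutations: int           # alleles - 1
    derived_count: int | None = None


@dataclass
class PolymorphismTable:
    sites: list[PolymorphicSite]
    n: int

    @property
    def S(self) -> int:
        return len(self.sites)

    @property
    def eta(self) -> int:
        return sum(s.n_mutations for s in self.sites)

    @property
    def n_singletons(self) -> int:
        return sum(s.singleton for s in self.sites)

    @property
    def n_parsimony_informative(self) -> int:
        return sum(s.parsimony_informative for s in self.sites)

    def count(self, site_class: str) -> int:
        """Number of variable sites in a class ('all'/'syn'/'nonsyn'/'silent')."""
        if site_class == "all":
            return self.S
        label = {"syn": "synonymous", "silent": "synonymous",
                 "nonsyn": "nonsynonymous"}[site_class]
        return sum(s.site_class == label for s in self.sites)

    def eta_count(self, site_class: str) -> int:
        if site_class == "all":
            return self.eta
        label = {"syn": "synonymous", "silent": "synonymous",
                 "nonsyn": "nonsynonymous"}[site_class]
        return sum(s.n_mutations for s in self.sites if s.site_class == label)

    def singletons(self, site_class: str = "all") -> int:
        if site_class == "all":
            return self.n_singletons
        label = {"syn": "synonymous", "silent": "synonymous",
                 "nonsyn": "nonsynonymous"}[site_class]
        return sum(s.singleton for s in self.sites if s.site_class == label)

    def fractional_counts(self) -> tuple[float, float]:
        """(synonymous, nonsynonymous) mutation tallies with pathway
        fractions kept fractional."""
        syn = sum(s.n_mutations * s.syn_fraction for s in self.sites)
        return syn, sum(s.n_mutations for s in self.sites) - syn

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "position_1based": s.position + 1,
                "codon_1based": s.codon_index + 1,
                "alleles": ",".join(f"{a}:{c}" for a, c in sorted(s.alleles.items())),
                "class": s.site_class,
                "syn_fraction": s.syn_fraction,
                "singleton": s.singleton,
                "parsimony_informative": s.parsimony_informative,
                "derived_count": s.derived_count,
            }
            for s in self.sites
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DiversityEstimates:
    site_class: str
    n: int
    L: float
    S: int
    eta: int
    pi: float            # per site, raw
    pi_jc: float | None  # per site, Jukes-Cantor corrected pairwise average
    theta_w: float       # per site
    pi_total: float      # mean pairwise difference count (not per site)


@dataclass(frozen=True)
class UnfoldedSFS:
    xi: np.ndarray       # xi[i] = derived variants at count i, index 0 unused
    n: int
    excluded_sites: dict[str, int] = field(default_factory=dict)

    @property
    def n_polarized(self) -> int:
        return int(self.xi[1:].sum())

    @property
    def segregating(self) -> int:
        return self.n_polarized


# ---------------------------------------------------------------------------
# the per-site decomposition engine
# ---------------------------------------------------------------------------


class AlignmentSummary:
    """Cached per-site decomposition of an alignment's ingroup.

    Attributes
    ----------
    site_syn, site_nonsyn : per nt position fractional site counts,
        averaged over ingroup sequences.
    diff_all, diff_syn, diff_nonsyn : per nt position difference counts
        summed over all unordered ingroup pairs.
    pair_all, pair_syn, pair_nonsyn : per-pair total difference counts
        (condensed upper-triangle order), for Jukes-Cantor correction.
    """

    def __init__(self, aln: CodingAlignment):
        self.aln = aln
        self.n = aln.n_ingroup
        self.table = classify_polymorphisms(aln)
        cmap = codon_map(aln.table_id)
        ingroup = aln.ingroup
        L = aln.length
        n = self.n

        self.site_syn = np.zeros(L)
        self.site_nonsyn = np.zeros(L)
        frac_cache: dict[str, tuple[float, float, float]] = {}
        for rec in ingroup:
            for j in range(aln.n_codons):
                codon = rec.seq[3 * j : 3 * j + 3]
                if codon not in frac_cache:
                    if cmap[codon] == "*":
                        raise InternalStopError(
                            f"record {rec.id!r}: internal stop codon at codon "
                            f"{j + 1}"
                        )
                    # split the codon's fractional sites over its 3 positions
                    per_pos = _per_position_site_fractions(codon, aln.table_id)
                    frac_cache[codon] = per_pos
                per_pos = frac_cache[codon]
                for k in range(3):
                    self.site_syn[3 * j + k] += per_pos[k]
                    self.site_nonsyn[3 * j + k] += 1.0 - per_pos[k]
        self.site_syn /= n
        self.site_nonsyn /= n

        npairs = n * (n - 1) // 2
        self.npairs = npairs
        self.diff_all = np.zeros(L)
        self.diff_syn = np.zeros(L)
        self.diff_nonsyn = np.zeros(L)
        self.pair_all = np.zeros(npairs)
        self.pair_syn = np.zeros(npairs)
        self.pair_nonsyn = np.zeros(npairs)
        pair_index = _pair_index_matrix(n)

        var_codons = sorted({s.codon_index for s in self.table.sites})
        for j in var_codons:
            codons = [rec.seq[3 * j : 3 * j + 3] for rec in ingroup]
            groups: dict[str, list[int]] = {}
            for idx, c in enumerate(codons):
                groups.setdefault(c, []).append(idx)
            variants = sorted(groups)
            for a_i in range(len(variants)):
                for b_i in range(a_i + 1, len(variants)):
                    ca, cb = variants[a_i], variants[b_i]
                    prof = pathway_profile(ca, cb, aln.table_id)
                    members_a, members_b = groups[ca], groups[cb]
                    pidx = pair_index[np.ix_(members_a, members_b)].ravel()
                    w = len(members_a) * len(members_b)
                    for pos, (s_frac, n_frac) in prof.items():
                        col = 3 * j + pos
                        self.diff_all[col] += w
                        self.diff_syn[col] += w * s_frac
                        self.diff_nonsyn[col] += w * n_frac
                        self.pair_all[pidx] += 1.0
                        self.pair_syn[pidx] += s_frac
                        self.pair_nonsyn[pidx] += n_frac

    # -- site/diff selectors -------------------------------------------
    def sites_in(self, site_class: str, mask: np.ndarray | None = None) -> float:
        arr = {
            "all": np.ones_like(self.site_syn),
            "syn": self.site_syn,
            "silent": self.site_syn,
            "nonsyn": self.site_nonsyn,
        }[site_class]
        return float(arr.sum() if mask is None else arr[mask].sum())

    def diffs_in(self, site_class: str, mask: np.ndarray | None = None) -> float:
        arr = {
            "all": self.diff_all,
            "syn": self.diff_syn,
            "silent": self.diff_syn,
            "nonsyn": self.diff_nonsyn,
        }[site_class]
        return float(arr.sum() if mask is None else arr[mask].sum())

    def pair_diffs(self, site_class: str) -> np.ndarray:
        return {
            "all": self.pair_all,
            "syn": self.pair_syn,
            "silent": self.pair_syn,
            "nonsyn": self.pair_nonsyn,
        }[site_class]

    # -- statistics -----------------------------------------------------
    def pi_raw(self, site_class: str = "all", mask: np.ndarray | None = None) -> float:
        L = self.sites_in(site_class, mask)
        if L == 0:
            return math.nan
        return self.diffs_in(site_class, mask) / self.npairs / L

    def pi_jc(self, site_class: str = "all") -> float:
        L = self.sites_in(site_class)
        if L == 0:
            return math.nan
        p = self.pair_diffs(site_class) / L
        if np.any(p >= 0.75):
            raise ValueError(
                "Jukes-Cantor correction undefined: pairwise difference "
                "proportion >= 3/4"
            )
        return float(np.mean(-0.75 * np.log1p(-4.0 * p / 3.0)))

    def pi_total(self, site_class: str = "all", mask: np.ndarray | None = None) -> float:
        """Mean pairwise difference *count* (Tajima's k-hat) in a class."""
        return self.diffs_in(site_class, mask) / self.npairs

    def S_class(self, site_class: str, mask: np.ndarray | None = None) -> int:
        label = {"syn": "synonymous", "silent": "synonymous",
                 "nonsyn": "nonsynonymous"}.get(site_class)
        count = 0
        for s in self.table.sites:
            if mask is not None and not mask[s.position]:
                continue
            if label is None or s.site_class == label:
                count += 1
        return count

    def diversity(self, site_class: str = "all", jc: bool = True) -> DiversityEstimates:
        L = self.sites_in(site_class)
        S = self.S_class(site_class)
        label = {"syn": "synonymous", "silent": "synonymous",
                 "nonsyn": "nonsynonymous"}.get(site_class)
        eta = sum(
            s.n_mutations
            for s in self.table.sites
            if label is None or s.site_class == label
        )
        return DiversityEstimates(
            site_class=site_class,
            n=self.n,
            L=L,
            S=S,
            eta=eta,
            pi=self.pi_raw(site_class),
            pi_jc=self.pi_jc(site_class) if jc else None,
            theta_w=watterson_theta(S, self.n, L) if L > 0 else math.nan,
            pi_total=self.pi_total(site_class),
        )


def _per_position_site_fractions(codon: str, table_id: int) -> tuple[float, float, float]:
    """Synonymous fraction of each of the codon's three positions."""
    cmap = codon_map(table_id)
    aa = cmap[codon]
    out = []
    for pos in range(3):
        n_syn = n_valid = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if cmap[alt] == "*":
                continue
            n_valid += 1
            n_syn += cmap[alt] == aa
        out.append(n_syn / n_valid if n_valid else 0.0)
    total_syn, _ = codon_site_fractions(codon, table_id)
    assert abs(sum(out) - total_syn) < 1e-9
    return tuple(out)


def _pair_index_matrix(n: int) -> np.ndarray:
    """Map (i, j) -> condensed pair index, symmetric."""
    idx = np.zeros((n, n), dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            idx[i, j] = idx[j, i] = k
            k += 1
    return idx


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def count_sites_neigojobori(aln: CodingAlignment) -> SiteClassCounts:
    """Fractional synonymous/nonsynonymous site counts, averaged over all
    ingroup sequences (Nei–Gojobori 1986)."""
    cmap = codon_map(aln.table_id)
    syn_total = 0.0
    for rec in aln.ingroup:
        for j in range(aln.n_codons):
            codon = rec.seq[3 * j : 3 * j + 3]
            if cmap[codon] == "*":
                raise InternalStopError(
                    f"record {rec.id!r}: internal stop codon at codon {j + 1}"
                )
            syn, _ = codon_site_fractions(codon, aln.table_id)
            syn_total += syn
    n = aln.n_ingroup
    L_total = float(aln.length)
    L_syn = syn_total / n
    return SiteClassCounts(L_total=L_total, L_syn=L_syn, L_nonsyn=L_total - L_syn)


def classify_polymorphisms(aln: CodingAlignment) -> PolymorphismTable:
    """Tabulate variable ingroup columns with codon-context classification.

    Each non-major allele is one mutation; its synonymous fraction is the
    pathway-averaged fraction at that position between the major-allele
    codon and the (majority) codon carrying the allele.  Sites are
    labelled by the majority pathway fraction (ties to nonsynonymous).
    """
    ingroup = aln.ingroup
    n = len(ingroup)
    mat = np.frombuffer(
        "".join(r.seq for r in ingroup).encode(), dtype="S1"
    ).reshape(n, aln.length)
    variable = [
        j for j in range(aln.length) if len(set(mat[:, j].tobytes())) > 1
    ]
    sites: list[PolymorphicSite] = []
    for col in variable:
        codon_idx = col // 3
        pos_in_codon = col % 3
        nts = [chr(b[0]) for b in mat[:, col]]
        allele_counts = Counter(nts)
        codons = [r.seq[3 * codon_idx : 3 * codon_idx + 3] for r in ingroup]
        # majority codon context for each nucleotide allele at this column
        context: dict[str, str] = {}
        for allele in allele_counts:
            carrier = Counter(c for c, nt in zip(codons, nts) if nt == allele)
            context[allele] = min(
                carrier, key=lambda c: (-carrier[c], c)
            )
        major = min(allele_counts, key=lambda a: (-allele_counts[a], a))
        syn_sum = 0.0
        n_mut = 0
        for allele in allele_counts:
            if allele == major:
                continue
            prof = pathway_profile(context[major], context[allele], aln.table_id)
            s_frac, _ = prof.get(pos_in_codon, (0.0, 1.0))
            syn_sum += s_frac
            n_mut += 1
        syn_fraction = syn_sum / n_mut
        counts = sorted(allele_counts.values())
        sites.append(
            PolymorphicSite(
                position=col,
                codon_index=codon_idx,
                alleles=dict(allele_counts),
                syn_fraction=syn_fraction,
                site_class="synonymous" if syn_fraction > 0.5 else "nonsynonymous",
                singleton=len(counts) == 2 and counts[0] == 1,
                parsimony_informative=sum(c >= 2 for c in counts) >= 2,
                n_mutations=n_mut,
            )
        )
    return PolymorphismTable(sites=sites, n=n)


def pi(aln: CodingAlignment, site_class: str = "all", jc: bool = False) -> float:
    """Per-site nucleotide diversity in a site class.

    Raw: total class differences over all unordered pairs divided by the
    class site count.  With ``jc`` each pair's difference proportion is
    Jukes-Cantor corrected before averaging.
    """
    summary = AlignmentSummary(aln)
    return summary.pi_jc(site_class) if jc else summary.pi_raw(site_class)


def watterson_theta(S: int, n: int, L: float) -> float:
    """Per-site Watterson estimator S / (a1 L)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if L <= 0:
        raise ValueError("need L > 0")
    a1 = sum(1.0 / i for i in range(1, n))
    return S / (a1 * L)


def polarize(aln: CodingAlignment, outgroup_id: str | None = None) -> UnfoldedSFS:
    """Unfolded SFS from outgroup polarization.

    Biallelic ingroup sites where the outgroup carries one of the two
    alleles are polarized (outgroup allele = ancestral).  Sites that are
    triallelic in the ingroup, or where the outgroup is gapped/N or
    carries a third allele, are excluded and counted by reason.
    """
    og_id = outgroup_id or aln.outgroup_id
    if og_id is None:
        raise ValueError("no outgroup available for polarization")
    og = next((r for r in aln.records if r.id == og_id), None)
    if og is None:
        raise ValueError(f"outgroup id {og_id!r} not in alignment")
    ingroup = [r for r in aln.records if r.id != og_id]
    n = len(ingroup)
    xi = np.zeros(n, dtype=np.int64)
    excluded = {"multiallelic": 0, "outgroup_missing": 0, "outgroup_third_allele": 0}
    for col in range(aln.length):
        alleles = Counter(r.seq[col] for r in ingroup)
        if len(alleles) < 2:
            continue
        if len(alleles) > 2:
            excluded["multiallelic"] += 1
            continue
        anc = og.seq[col]
        if anc in "N-":
            excluded["outgroup_missing"] += 1
            continue
        if anc not in alleles:
            excluded["outgroup_third_allele"] += 1
            continue
        derived = next(a for a in alleles if a != anc)
        xi[alleles[derived]] += 1
    return UnfoldedSFS(xi=xi, n=n, excluded_sites=excluded)


def sliding_window(
    aln: CodingAlignment,
    window_bp: int = 10,
    step_bp: int = 1,
    stats: tuple[str, ...] = ("pi_nonsyn", "tajima_d_nonsyn"),
) -> pd.DataFrame:
    """Window-resolved statistics; site classes come from the full codon
    context.  Windows with zero class sites yield NaN, not zero."""
    from .neutrality import tajima_d  # local import avoids cycle at import time

    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if step_bp < 1:
        raise ValueError("step_bp must be >= 1")
    if window_bp > aln.length:
        raise ValueError("window longer than alignment")
    summary = AlignmentSummary(aln)
    rows = []
    for start in range(0, aln.length - window_bp + 1, step_bp):
        mask = np.zeros(aln.length, dtype=bool)
        mask[start : start + window_bp] = True
        row: dict[str, float] = {"start_1based": start + 1, "end_1based": start + window_bp}
        for stat in stats:
            name, _, cls = stat.partition("_")
            if name == "pi":
                row[stat] = summary.pi_raw(cls, mask)
            elif stat.startswith("tajima_d"):
                cls = stat.removeprefix("tajima_d").lstrip("_") or "all"
                S = summary.S_class(cls, mask)
                if S == 0 or summary.n < 4:
                    row[stat] = math.nan
                else:
                    row[stat] = tajima_d(S, summary.pi_total(cls, mask), summary.n)
            else:
                raise ValueError(f"unknown window statistic {stat!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def region_stats(
    aln: CodingAlignment,
    regions: list,
    site_classes: tuple[str, ...] = ("all", "nonsyn"),
    jc: bool = True,
) -> pd.DataFrame:
    """Diversity and Tajima's D per named region (codon-column
    concatenation of each region's residues)."""
    from .neutrality import tajima_d

    rows = []
    for region in regions:
        if region.end_aa > aln.n_codons:
            raise ValueError(
                f"region {region.name!r} [{region.start_aa}, {region.end_aa}) "
                f"outside alignment of {aln.n_codons} codons"
            )
        sub = aln.subset_codons(list(range(region.start_aa, region.end_aa)))
        summary = AlignmentSummary(sub)
        for cls in site_classes:
            est = summary.diversity(cls, jc=jc)
            d = (
                tajima_d(est.S, est.pi_total, est.n)
                if est.S > 0 and est.n >= 4
                else math.nan
            )
            rows.append(
                {
                    "region": region.name,
                    "site_class": cls,
                    "L": est.L,
                    "S": est.S,
                    "eta": est.eta,
                    "pi": est.pi,
                    "pi_jc": est.pi_jc,
                    "theta_w": est.theta_w,
                    "tajima_d": d,
                }
            )
    return pd.DataFrame(rows)
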