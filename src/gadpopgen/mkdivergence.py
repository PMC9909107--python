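"""McDonald–Kreitman-family interspecies tests.

Contrasts within-species polymorphism (Pn, Ps) against fixed
interspecific differences (Dn, Ds) in a 2x2 table, with the derived
summaries: neutrality index NI = (Pn/Ps)/(Dn/Ds), the proportion of
adaptive substitutions alpha = 1 - NI, and the direction of selection
DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps).  Undefined ratios are reported as NaN
(no pseudo-counts); Fisher's exact p is always computable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats as sps

from .codons import codon_map, pathway_profile
from .popstats import classify_polymorphisms
from .seqio import CodingAlignment, SequenceRecord, complete_deletion


@dataclass(frozen=True)
class MKTable:
    Pn: int
    Ps: int
    Dn: int
    Ds: int
    NI: float = math.nan
    alpha: float = math.nan
    DoS: float = math.nan
    fisher_p: float = math.nan

    def __post_init__(self):
        for name in ("Pn", "Ps", "Dn", "Ds"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


def count_fixed_differences(
    ingroup: CodingAlignment, comparator: SequenceRecord
) -> tuple[int, int]:
    """(Dn, Ds): fixed nonsynonymous/synonymous differences vs a
    comparator sequence aligned to the ingroup coordinates.

    A site is fixed iff the ingroup is monomorphic there and differs
    from the comparator; classification uses pathway averaging between
    the ingroup codon and the comparator codon (majority class, ties to
    nonsynonymous).  Ingroup-polymorphic sites belong to P, not D.
    """
    if len(comparator.seq) != ingroup.length:
        raise ValueError(
            f"comparator length {len(comparator.seq)} != alignment length "
            f"{ingroup.length}"
        )
    cmap = codon_map(ingroup.table_id)
    dn = ds = 0
    for j in range(ingroup.n_codons):
        in_codons = {r.seq[3 * j : 3 * j + 3] for r in ingroup.ingroup}
        comp = comparator.seq[3 * j : 3 * j + 3]
        if cmap.get(comp) is None:
            continue  # comparator codon gapped/ambiguous: joint deletion missed it
        poly_positions = set()
        if len(in_codons) > 1:
            ref = next(iter(in_codons))
            for c in in_codons:
                poly_positions |= {k for k in range(3) if c[k] != ref[k]}
        codon = next(iter(in_codons))
        prof = pathway_profile(codon, comp, ingroup.table_id)
        for pos, (s_frac, n_frac) in prof.items():
            if pos in poly_positions:
                continue  # polymorphic in the ingroup: not a fixed difference
            if any(c[pos] != comp[pos] for c in in_codons):
                if s_frac > 0.5:
                    ds += 1
                else:
                    dn += 1
    return dn, ds


def mk_counts(
    ingroup: CodingAlignment,
    comparator: SequenceRecord,
    table_id: int | None = None,
) -> MKTable:
    """Build the full 2x2 table: joint complete deletion with the
    comparator so P and D share one site universe, then polymorphism and
    fixed-difference counts."""
    joint = CodingAlignment(
        records=tuple(ingroup.ingroup) + (comparator,),
        populations={},
        outgroup_id=comparator.id,
        table_id=table_id or ingroup.table_id,
    )
    joint = complete_deletion(joint)
    comp = joint.outgroup
    core = CodingAlignment(
        records=joint.ingroup,
        populations={},
        outgroup_id=None,
        table_id=joint.table_id,
    )
    table = classify_polymorphisms(core)
    pn = ps = 0
    for site in table.sites:
        if site.site_class == "synonymous":
            ps += site.n_mutations
        else:
            pn += site.n_mutations
    dn, ds = count_fixed_differences(core, comp)
    return MKTable(Pn=pn, Ps=ps, Dn=dn, Ds=ds)


def mk_test(tbl: MKTable) -> MKTable:
    """Fill NI, alpha, DoS and the two-tailed Fisher exact p."""
    ni = alpha = dos = math.nan
    if tbl.Ps > 0 and tbl.Dn > 0 and tbl.Ds > 0:
        ni = (tbl.Pn / tbl.Ps) / (tbl.Dn / tbl.Ds)
        alpha = 1.0 - ni
    if (tbl.Dn + tbl.Ds) > 0 and (tbl.Pn + tbl.Ps) > 0:
        dos = tbl.Dn / (tbl.Dn + tbl.Ds) - tbl.Pn / (tbl.Pn + tbl.Ps)
    _, p = sps.fisher_exact([[tbl.Pn, tbl.Ps], [tbl.Dn, tbl.Ds]],
                            alternative="two-sided")
    return replace(tbl, NI=ni, alpha=alpha, DoS=dos, fisher_p=float(p))


def interpret(tbl: MKTable, alpha_level: float = 0.05) -> str:
    """'positive_selection' | 'negative_selection' | 'neutral'."""
    if math.isnan(tbl.DoS):
        return "neutral"
    if tbl.fisher_p < alpha_level and tbl.DoS > 0:
        return "positive_selection"
    if tbl.fisher_p < alpha_level and tbl.DoS < 0:
        return "negative_selection"
    return "neutral"
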