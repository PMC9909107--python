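"""Codon-usage-bias indices: RSCU, CAI (Sharp & Li 1987) and CBI
(Bennetzen & Hall 1982), with Kazusa-format reference-table input.

The reference is a genome-wide codon usage table; relative adaptiveness
w of each codon is its RSCU divided by the maximum RSCU in its
synonymous family, and the optimal-codon set is the per-family argmax.
Single-codon families (Met, Trp under the bacterial code) carry no
choice information and are excluded from CAI and from the optimal set.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

from .codons import DEFAULT_TABLE_ID, codon_map

_W_FLOOR = 0.01  # relative adaptiveness floor for zero-count codons

_KAZUSA_ENTRY = re.compile(
    r"([ACGUTacgut]{3})\s+([0-9.]+)\s*\(\s*([0-9]+)\s*\)|([ACGUTacgut]{3})\s+([0-9.]+)\s+([0-9]+)"
)


@dataclass(frozen=True)
class CodonUsageReference:
    counts: dict[str, float]      # sense codon -> count
    rscu: dict[str, float]
    w: dict[str, float]           # relative adaptiveness in (0, 1]
    optimal: frozenset[str]       # per-family argmax codons
    table_id: int = DEFAULT_TABLE_ID


def _families(table_id: int) -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in codon_map(table_id).items():
        if aa != "*":
            fams.setdefault(aa, []).append(codon)
    return fams


def reference_from_counts(
    counts: dict[str, float], table_id: int = DEFAULT_TABLE_ID,
    w_floor: float = _W_FLOOR,
) -> CodonUsageReference:
    fams = _families(table_id)
    missing = {c for fam in fams.values() for c in fam} - set(counts)
    if missing:
        raise ValueError(f"codon usage table missing codons: {sorted(missing)}")
    rscu: dict[str, float] = {}
    w: dict[str, float] = {}
    optimal = set()
    for aa, fam in fams.items():
        total = sum(counts[c] for c in fam)
        k = len(fam)
        for c in fam:
            rscu[c] = counts[c] * k / total if total > 0 else 1.0
        top = max(rscu[c] for c in fam)
        for c in fam:
            w[c] = max(rscu[c] / top, w_floor) if top > 0 else 1.0
        # all per-family maxima are optimal (ties allowed)
        for c in fam:
            if rscu[c] == top:
                optimal.add(c)
    return CodonUsageReference(
        counts=dict(counts), rscu=rscu, w=w, optimal=frozenset(optimal),
        table_id=table_id,
    )


def read_kazusa_table(
    path: str | Path, table_id: int = DEFAULT_TABLE_ID
) -> CodonUsageReference:
    """Parse a Kazusa-style codon usage table.

    Accepts both the classic ``UUU 17.6(  714298)`` block layout and
    plain whitespace-separated (codon, per-thousand, count) triplets;
    U/T are interchangeable.  All 64 codons must be present.
    """
    counts: dict[str, float] = {}
    found_any = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            hits = list(_KAZUSA_ENTRY.finditer(line))
            if not hits:
                raise ValueError(f"{path}:{lineno}: unparseable codon usage line")
            for m in hits:
                codon = (m.group(1) or m.group(4)).upper().replace("U", "T")
                count = float(m.group(3) or m.group(6))
                counts[codon] = count
                found_any = True
    if not found_any:
        raise ValueError(f"{path}: no codon entries found")
    cmap = codon_map(table_id)
    missing = set(cmap) - set(counts)
    if missing:
        raise ValueError(f"{path}: missing codons {sorted(missing)}")
    sense = {c: counts[c] for c in cmap if cmap[c] != "*"}
    return reference_from_counts(sense, table_id)


def _gene_codons(seq: str, table_id: int) -> list[str]:
    if len(seq) % 3:
        raise ValueError("CDS length not divisible by 3")
    cmap = codon_map(table_id)
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and cmap.get(codons[-1]) == "*":
        codons = codons[:-1]
    for k, c in enumerate(codons):
        if cmap.get(c) == "*":
            raise ValueError(f"internal stop codon at codon {k + 1}")
        if c not in cmap:
            raise ValueError(f"ambiguous or gapped codon {c!r} at codon {k + 1}")
    return codons


def cai(gene, ref: CodonUsageReference) -> float:
    """Codon adaptation index: geometric mean of w over the gene's
    codons, excluding single-codon families (Met, Trp) and stops."""
    seq = gene if isinstance(gene, str) else gene.seq
    fams = _families(ref.table_id)
    singles = {fam[0] for fam in fams.values() if len(fam) == 1}
    codons = [c for c in _gene_codons(seq, ref.table_id) if c not in singles]
    if not codons:
        raise ValueError("no informative codons for CAI")
    return math.exp(sum(math.log(ref.w[c]) for c in codons) / len(codons))


def cbi(gene, ref: CodonUsageReference) -> float:
    """Codon bias index (Bennetzen & Hall 1982):
    (N_opt - N_rand) / (N_tot - N_rand), where N_rand is the expected
    number of optimal codons under uniform synonymous choice given the
    gene's amino-acid composition."""
    seq = gene if isinstance(gene, str) else gene.seq
    cmap = codon_map(ref.table_id)
    fams = _families(ref.table_id)
    fam_size = {aa: len(f) for aa, f in fams.items()}
    n_opt_fam = {
        aa: sum(c in ref.optimal for c in f) for aa, f in fams.items()
    }
    singles = {aa for aa, f in fams.items() if len(f) == 1}
    n_opt = n_tot = 0
    n_rand = 0.0
    for c in _gene_codons(seq, ref.table_id):
        aa = cmap[c]
        if aa in singles:
            continue
        n_tot += 1
        n_opt += c in ref.optimal
        n_rand += n_opt_fam[aa] / fam_size[aa]
    if n_tot == 0 or abs(n_tot - n_rand) < 1e-12:
        return math.nan
    return (n_opt - n_rand) / (n_tot - n_rand)
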