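"""Biochemistry of replacement changes: residue classification,
net charge as a function of pH, and isoelectric points.

The residue class/charge/polarity table is frozen from standard
biochemistry references (note the 'sulfuric' class for C and M used in
the amino-acid-change tallies).  The charge model is the usual
Henderson–Hasselbalch sum over ionizable side chains plus the two
termini; pKa values default to the ExPASy-style set and the model is
pluggable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import defaultdict

from .seqio import SequenceRecord

# residue -> (class, charge at pH 7, polarity)
AA_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "G": ("aliphatic", "0", "nonpolar"),
    "A": ("aliphatic", "0", "nonpolar"),
    "V": ("aliphatic", "0", "nonpolar"),
    "L": ("aliphatic", "0", "nonpolar"),
    "I": ("aliphatic", "0", "nonpolar"),
    "F": ("aromatic", "0", "nonpolar"),
    "W": ("aromatic", "0", "nonpolar"),
    "Y": ("aromatic", "0", "polar"),
    "K": ("basic", "+", "polar"),
    "R": ("basic", "+", "polar"),
    "H": ("basic", "+", "polar"),
    "D": ("acidic", "-", "polar"),
    "E": ("acidic", "-", "polar"),
    "N": ("amide", "0", "polar"),
    "Q": ("amide", "0", "polar"),
    "S": ("hydroxylic", "0", "polar"),
    "T": ("hydroxylic", "0", "polar"),
    "C": ("sulfuric", "0", "nonpolar"),  # hydrophobicity-scale convention
    "M": ("sulfuric", "0", "nonpolar"),
    "P": ("imino", "0", "nonpolar"),
}

IONIZABLE = set("DECYHKR")


@dataclass(frozen=True)
class ChargeModel:
    """pKa set for the titratable groups (ExPASy-style defaults)."""

    pka_nterm: float = 7.5
    pka_cterm: float = 3.55
    pka_side: dict[str, float] = field(
        default_factory=lambda: {
            "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
            "H": 5.98, "K": 10.0, "R": 12.0,
        }
    )

    def __post_init__(self):
        for name, pka in [("N-terminus", self.pka_nterm),
                          ("C-terminus", self.pka_cterm),
                          *self.pka_side.items()]:
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa for {name} out of (0, 14): {pka}")


DEFAULT_CHARGE_MODEL = ChargeModel()

BASIC = set("KRH")
ACIDIC = set("DECY")  # acid-titrating side chains (C and Y deprotonate)


@dataclass(frozen=True)
class ReplacementChange:
    position: int            # 1-based residue position
    from_aa: str
    to_aa: str
    populations: tuple[str, ...]
    count: int
    singleton: bool
    conservative: bool
    changed_attributes: tuple[str, ...]


def classify_change(from_aa: str, to_aa: str) -> tuple[bool, dict[str, str]]:
    """Conservative iff class, charge and polarity are all unchanged.

    Returns (conservative, changed attribute -> 'old->new').
    """
    for aa in (from_aa, to_aa):
        if aa not in AA_PROPERTIES:
            raise ValueError(f"unknown residue {aa!r}")
    changed: dict[str, str] = {}
    for name, a, b in zip(
        ("class", "charge", "polarity"),
        AA_PROPERTIES[from_aa],
        AA_PROPERTIES[to_aa],
    ):
        if a != b:
            changed[name] = f"{a}->{b}"
    return not changed, changed


def tally_changes(
    alignments_by_population: dict[str, list[SequenceRecord]],
    wild_type: SequenceRecord,
) -> list[ReplacementChange]:
    """Tally amino-acid changes relative to a wild-type sequence.

    Independent occurrences of the same positional change in different
    populations are summed; a change is a singleton when it is carried
    by exactly one sequence overall.
    """
    occurrences: dict[tuple[int, str, str], dict[str, int]] = defaultdict(dict)
    for pop, records in alignments_by_population.items():
        for rec in records:
            if len(rec.seq) != len(wild_type.seq):
                raise ValueError(
                    f"record {rec.id!r} length {len(rec.seq)} != wild type "
                    f"{len(wild_type.seq)}"
                )
            for k, (wt, aa) in enumerate(zip(wild_type.seq, rec.seq)):
                if aa == wt or aa in "-X" or wt in "-X":
                    continue
                key = (k + 1, wt, aa)
                occurrences[key][pop] = occurrences[key].get(pop, 0) + 1
    changes = []
    for (pos, wt, aa), pops in sorted(occurrences.items()):
        total = sum(pops.values())
        conservative, changed = classify_change(wt, aa)
        changes.append(
            ReplacementChange(
                position=pos,
                from_aa=wt,
                to_aa=aa,
                populations=tuple(sorted(pops)),
                count=total,
                singleton=total == 1,
                conservative=conservative,
                changed_attributes=tuple(sorted(changed)),
            )
        )
    return changes


def consensus_wild_type(records: list[SequenceRecord],
                        rec_id: str = "wild_type") -> SequenceRecord:
    """Majority-consensus amino-acid sequence (column-wise plurality,
    ties broken alphabetically)."""
    from collections import Counter

    length = len(records[0].seq)
    cols = []
    for k in range(length):
        counts = Counter(r.seq[k] for r in records)
        cols.append(min(counts, key=lambda a: (-counts[a], a)))
    return SequenceRecord(rec_id, "".join(cols), "aa")


def net_charge(
    seq: SequenceRecord | str,
    pH: float,
    model: ChargeModel = DEFAULT_CHARGE_MODEL,
) -> float:
    """Modeled net charge Q(pH): positive terms for protonated bases and
    the N-terminus, negative for deprotonated acids and the C-terminus."""
    s = seq if isinstance(seq, str) else seq.seq
    if "-" in s:
        raise ValueError("net charge needs a gap-free sequence")
    q = 1.0 / (1.0 + 10.0 ** (pH - model.pka_nterm))
    q -= 1.0 / (1.0 + 10.0 ** (model.pka_cterm - pH))
    for aa in s:
        pka = model.pka_side.get(aa)
        if pka is None:
            continue
        if aa in BASIC:
            q += 1.0 / (1.0 + 10.0 ** (pH - pka))
        else:
            q -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return q


def isoelectric_point(
    seq: SequenceRecord | str,
    model: ChargeModel = DEFAULT_CHARGE_MODEL,
    tol: float = 1e-4,
) -> float:
    """The unique pH in (0, 14) where Q(pH) = 0, by bisection.

    Q is strictly decreasing in pH (every term is), so the root exists
    and is unique: Q(0) >= +1 (N-terminus), Q(14) <= -1 (C-terminus).
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, model) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def titration_table(
    seq: SequenceRecord | str,
    model: ChargeModel = DEFAULT_CHARGE_MODEL,
    ph_start: float = 4.0,
    ph_stop: float = 7.0,
    ph_step: float = 0.25,
) -> list[tuple[float, float]]:
    """(pH, net charge) rows over the acidic-range pH grid."""
    rows = []
    ph = ph_start
    while ph <= ph_stop + 1e-9:
        rows.append((round(ph, 2), net_charge(seq, ph, model)))
        ph += ph_step
    return rows
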