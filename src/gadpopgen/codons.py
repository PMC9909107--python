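"""Genetic-code helpers: translation, one-step neighbourhoods and
Nei–Gojobori pathway bookkeeping.

Everything is parameterised by an NCBI translation table id (default 11,
the bacterial/plastid code) so the same machinery serves other organisms.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
DEFAULT_TABLE_ID = 11


@lru_cache(maxsize=None)
def codon_map(table_id: int = DEFAULT_TABLE_ID) -> dict[str, str]:
    """Codon -> amino acid (one letter), with stop codons mapped to '*'."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@lru_cache(maxsize=None)
def sense_codons(table_id: int = DEFAULT_TABLE_ID) -> tuple[str, ...]:
    cmap = codon_map(table_id)
    return tuple(sorted(c for c, aa in cmap.items() if aa != "*"))


def translate_codon(codon: str, table_id: int = DEFAULT_TABLE_ID) -> str:
    return codon_map(table_id)[codon]


def is_stop(codon: str, table_id: int = DEFAULT_TABLE_ID) -> bool:
    return codon_map(table_id)[codon] == "*"


@lru_cache(maxsize=None)
def codon_site_fractions(
    codon: str, table_id: int = DEFAULT_TABLE_ID
) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each of the three positions contributes the fraction of its one-step
    changes that are synonymous; mutations creating a stop codon are
    excluded from the denominator (Nei & Gojobori convention).  A position
    whose every change creates a stop contributes a full nonsynonymous
    site.
    """
    cmap = codon_map(table_id)
    aa = cmap[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if cmap[alt] == "*":
                continue
            n_valid += 1
            if cmap[alt] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def pathway_profile(
    c1: str, c2: str, table_id: int = DEFAULT_TABLE_ID
) -> dict[int, tuple[float, float]]:
    """Per-position (synonymous, nonsynonymous) difference fractions
    between two codons.

    Codons differing at several positions are resolved by averaging with
    equal weight over all orderings of the single-nucleotide steps whose
    intermediates are not stop codons.  If every ordering passes through
    a stop, all orderings are used (standard fallback).  The values for
    each differing position sum to 1, so summing the profile reproduces
    the Nei–Gojobori pairwise (sd, nd) counts.
    """
    cmap = codon_map(table_id)
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return {}
    profiles: list[dict[int, tuple[float, float]]] = []
    stopfree: list[bool] = []
    for order in permutations(diff_positions):
        current = c1
        prof: dict[int, tuple[float, float]] = {}
        ok = True
        for step, pos in enumerate(order):
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if cmap[nxt] == "*" and step < len(order) - 1:
                ok = False
            synonymous = cmap[nxt] == cmap[current]
            prof[pos] = (1.0, 0.0) if synonymous else (0.0, 1.0)
            current = nxt
        # a stop *endpoint* (c2 itself) is the caller's problem, not a
        # pathway intermediate; only flag intermediate stops
        profiles.append(prof)
        stopfree.append(ok)
    use = [p for p, ok in zip(profiles, stopfree) if ok] or profiles
    out: dict[int, tuple[float, float]] = {}
    for pos in diff_positions:
        s = sum(p[pos][0] for p in use) / len(use)
        n = sum(p[pos][1] for p in use) / len(use)
        out[pos] = (s, n)
    return out


def codon_diff_counts(
    c1: str, c2: str, table_id: int = DEFAULT_TABLE_ID
) -> tuple[float, float]:
    """Pairwise (sd, nd): pathway-averaged synonymous and nonsynonymous
    difference counts between two codons."""
    prof = pathway_profile(c1, c2, table_id)
    return (
        sum(s for s, _ in prof.values()),
        sum(n for _, n in prof.values()),
    )
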