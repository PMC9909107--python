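import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles importable

from gadpopgen.seqio import CodingAlignment, SequenceRecord
from gadpopgen.codons import sense_codons


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_coding_alignment(
    rng,
    n: int = 6,
    n_codons: int = 50,
    mutation_rate: float = 0.02,
    outgroup: bool = False,
    table_id: int = 11,
) -> CodingAlignment:
    """Random stop-free codon-phased alignment: a random sense-codon
    backbone with sprinkled single-nucleotide variants (stop-creating
    variants skipped)."""
    from gadpopgen.codons import codon_map

    cmap = codon_map(table_id)
    codons = sense_codons(table_id)
    backbone = [codons[i] for i in rng.integers(0, len(codons), n_codons)]
    total = n + (1 if outgroup else 0)
    rows = [list("".join(backbone)) for _ in range(total)]
    L = 3 * n_codons
    for pos in range(L):
        for r in range(total):
            if rng.random() < mutation_rate:
                old = rows[r][pos]
                new = "ACGT".replace(old, "")[rng.integers(0, 3)]
                cstart = pos - pos % 3
                codon = "".join(rows[r][cstart : cstart + 3])
                alt = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
                if cmap[alt] != "*":
                    rows[r][pos] = new
    records = [
        SequenceRecord(f"s{k}", "".join(rows[k]), "nt") for k in range(n)
    ]
    populations = {r.id: f"pop{k % 3}" for k, r in enumerate(records)}
    outgroup_id = None
    if outgroup:
        records.append(SequenceRecord("og", "".join(rows[-1]), "nt"))
        outgroup_id = "og"
    return CodingAlignment(
        records=tuple(records),
        populations=populations,
        outgroup_id=outgroup_id,
        table_id=table_id,
    )


@pytest.fixture
def small_alignment(rng):
    return random_coding_alignment(rng, n=6, n_codons=40)
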