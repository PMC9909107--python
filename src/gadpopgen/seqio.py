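"""Sequence and metadata I/O, codon-phased alignments, and the
complete-deletion gap policy.

The analysis operates on protein-coding alignments that stay in frame:
gaps are handled per *codon* column, amino-acid alignments are
back-translated onto their coding sequences, and any codon column with a
gap or an N in any record is removed everywhere (complete deletion).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .codons import DEFAULT_TABLE_ID, codon_map

NT_ALPHABET = set("ACGTN-")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX-*")


class AlphabetError(ValueError):
    """Sequence contains a character outside the declared alphabet."""


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence, nucleotide (``nt``) or amino acid (``aa``)."""

    id: str
    seq: str
    moltype: str = "nt"

    def __post_init__(self):
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        if self.moltype not in ("nt", "aa"):
            raise ValueError(f"moltype must be 'nt' or 'aa', got {self.moltype!r}")
        alphabet = NT_ALPHABET if self.moltype == "nt" else AA_ALPHABET
        for pos, ch in enumerate(self.seq):
            if ch not in alphabet:
                raise AlphabetError(
                    f"record {self.id!r}: illegal {self.moltype} character "
                    f"{ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass(frozen=True)
class RegionSpec:
    """A named residue interval, 0-based half-open in alignment coordinates."""

    name: str
    start_aa: int
    end_aa: int

    def __post_init__(self):
        if not (0 <= self.start_aa < self.end_aa):
            raise ValueError(
                f"region {self.name!r}: need 0 <= start < end, "
                f"got [{self.start_aa}, {self.end_aa})"
            )


@dataclass(frozen=True)
class CodingAlignment:
    """A codon-phased nucleotide alignment with population labels.

    ``column_map`` records, per retained codon column, the codon index in
    the original ingested alignment (identity until complete deletion).
    """

    records: tuple[SequenceRecord, ...]
    populations: dict[str, str] = field(default_factory=dict)
    outgroup_id: str | None = None
    table_id: int = DEFAULT_TABLE_ID
    column_map: tuple[int, ...] | None = None

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment has no records")
        length = len(self.records[0])
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")
        for r in self.records:
            if r.moltype != "nt":
                raise ValueError(f"record {r.id!r} is not nucleotide")
            if len(r) != length:
                raise ValueError(
                    f"record {r.id!r} length {len(r)} != {length}: not aligned"
                )
        if length % 3:
            raise ValueError(f"alignment length {length} not divisible by 3")
        if self.outgroup_id is not None and self.outgroup_id not in ids:
            raise ValueError(f"outgroup id {self.outgroup_id!r} not in alignment")
        ingroup = [i for i in ids if i != self.outgroup_id]
        if len(ingroup) < 2:
            raise ValueError("need at least 2 ingroup records")
        if self.populations:
            missing = [i for i in ingroup if i not in self.populations]
            if missing:
                raise ValueError(f"records without population label: {missing}")

    # -- basic geometry -------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def ingroup(self) -> tuple[SequenceRecord, ...]:
        return tuple(r for r in self.records if r.id != self.outgroup_id)

    @property
    def outgroup(self) -> SequenceRecord | None:
        if self.outgroup_id is None:
            return None
        return next(r for r in self.records if r.id == self.outgroup_id)

    @property
    def n_ingroup(self) -> int:
        return len(self.ingroup)

    def codon(self, record: SequenceRecord, j: int) -> str:
        return record.seq[3 * j : 3 * j + 3]

    def subset_codons(self, codon_indices: list[int]) -> "CodingAlignment":
        """New alignment restricted to the given codon columns (in order)."""
        if not codon_indices:
            raise ValueError("empty codon selection")
        for j in codon_indices:
            if not 0 <= j < self.n_codons:
                raise ValueError(f"codon index {j} out of range 0..{self.n_codons - 1}")
        new_records = tuple(
            replace(r, seq="".join(r.seq[3 * j : 3 * j + 3] for j in codon_indices))
            for r in self.records
        )
        src = self.column_map or tuple(range(self.n_codons))
        return replace(
            self,
            records=new_records,
            column_map=tuple(src[j] for j in codon_indices),
        )

    def select_populations(self, labels: set[str]) -> "CodingAlignment":
        """Restrict the ingroup to records from the given populations
        (the outgroup, if any, is kept)."""
        keep = tuple(
            r
            for r in self.records
            if r.id == self.outgroup_id or self.populations.get(r.id) in labels
        )
        return replace(self, records=keep)


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, moltype: str = "nt") -> list[SequenceRecord]:
    """Read a FASTA file into validated, uppercased records (file order)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        try:
            records.append(SequenceRecord(id=rec.id, seq=seq, moltype=moltype))
        except ValueError as exc:
            raise AlphabetError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_population_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (id, population); a header row is tolerated."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            rid, pop = row[0].strip(), row[1].strip()
            if lineno == 1 and rid.lower() in ("id", "strain", "sequence"):
                continue
            if not pop:
                raise ParseError(f"{path}:{lineno}: empty population label")
            if rid in mapping:
                raise ParseError(f"{path}:{lineno}: duplicate id {rid!r}")
            mapping[rid] = pop
    return mapping


def read_region_spec(path: str | Path) -> list[RegionSpec]:
    """Three-column TSV (name, start_aa, end_aa), 1-based inclusive in the
    file, converted to 0-based half-open; overlap is rejected."""
    regions: list[RegionSpec] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not row[0].strip():
                continue
            if len(row) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            name = row[0].strip()
            if lineno == 1 and not row[1].strip().isdigit():
                continue  # header
            try:
                start_1, end_1 = int(row[1]), int(row[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer bound") from exc
            regions.append(RegionSpec(name, start_1 - 1, end_1))
    intervals = sorted((r.start_aa, r.end_aa, r.name) for r in regions)
    for (s1, e1, n1), (s2, e2, n2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ParseError(f"regions {n1!r} and {n2!r} overlap")
    return regions


# ---------------------------------------------------------------------------
# alignment construction
# ---------------------------------------------------------------------------


def backtranslate_alignment(
    aa_alignment: list[SequenceRecord],
    cds: list[SequenceRecord],
    populations: dict[str, str] | None = None,
    outgroup_id: str | None = None,
    table_id: int = DEFAULT_TABLE_ID,
) -> CodingAlignment:
    """Thread unaligned coding sequences through an amino-acid alignment.

    Each amino-acid gap becomes a ``---`` codon gap; ungapping the output
    reproduces the input CDS exactly.  Terminal stop codons are stripped
    if present in *all* CDS records (mixed presence is an error), and each
    CDS must translate to its ungapped amino-acid row.
    """
    cds_by_id = {r.id: r for r in cds}
    if set(cds_by_id) != {r.id for r in aa_alignment}:
        raise ValueError("amino-acid alignment and CDS ids do not match one-to-one")
    cds = _strip_terminal_stops(list(cds), table_id)
    cds_by_id = {r.id: r for r in cds}
    cmap = codon_map(table_id)
    out: list[SequenceRecord] = []
    for aa_rec in aa_alignment:
        if aa_rec.moltype != "aa":
            raise ValueError(f"record {aa_rec.id!r}: expected amino-acid moltype")
        nt = cds_by_id[aa_rec.id]
        ungapped_aa = aa_rec.ungapped()
        if 3 * len(ungapped_aa) != len(nt.seq):
            raise ValueError(
                f"record {aa_rec.id!r}: CDS length {len(nt.seq)} is not 3x "
                f"ungapped amino-acid length {len(ungapped_aa)}"
            )
        chunks: list[str] = []
        k = 0
        for residue in aa_rec.seq:
            if residue == "-":
                chunks.append("---")
                continue
            codon = nt.seq[3 * k : 3 * k + 3]
            translated = cmap.get(codon, "X")
            if residue != "X" and translated != residue:
                raise ValueError(
                    f"record {aa_rec.id!r}: codon {codon} at residue {k + 1} "
                    f"translates to {translated}, alignment says {residue}"
                )
            chunks.append(codon)
            k += 1
        out.append(SequenceRecord(aa_rec.id, "".join(chunks), "nt"))
    return CodingAlignment(
        records=tuple(out),
        populations=populations or {},
        outgroup_id=outgroup_id,
        table_id=table_id,
    )


def make_alignment(
    records: list[SequenceRecord],
    populations: dict[str, str] | None = None,
    outgroup_id: str | None = None,
    table_id: int = DEFAULT_TABLE_ID,
) -> CodingAlignment:
    """Build a CodingAlignment from already codon-phased nt records,
    stripping terminal stop codons if all records carry one."""
    records = _strip_terminal_stops(list(records), table_id)
    return CodingAlignment(
        records=tuple(records),
        populations=populations or {},
        outgroup_id=outgroup_id,
        table_id=table_id,
    )


def _strip_terminal_stops(
    records: list[SequenceRecord], table_id: int
) -> list[SequenceRecord]:
    cmap = codon_map(table_id)

    def has_stop(r: SequenceRecord) -> bool:
        tail = r.seq[-3:]
        return len(r.seq) >= 3 and cmap.get(tail) == "*"

    flags = [has_stop(r) for r in records]
    if any(flags) and not all(flags):
        with_stop = [r.id for r, f in zip(records, flags) if f]
        raise ValueError(
            f"terminal stop codon present in some records only: {with_stop}"
        )
    if all(flags):
        records = [replace(r, seq=r.seq[:-3]) for r in records]
    return records


def complete_deletion(aln: CodingAlignment) -> CodingAlignment:
    """Remove every codon column containing a gap or N in any record.

    Column provenance is retained in ``column_map`` so report coordinates
    can refer to the ingested alignment.
    """
    keep: list[int] = []
    for j in range(aln.n_codons):
        clean = True
        for r in aln.records:
            codon = r.seq[3 * j : 3 * j + 3]
            if "-" in codon or "N" in codon:
                clean = False
                break
        if clean:
            keep.append(j)
    if not keep:
        raise ValueError("complete deletion removed every codon column")
    return aln.subset_codons(keep)
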