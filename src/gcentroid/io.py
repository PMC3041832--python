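"""Readers and writers for the external formats the toolkit touches.

FASTA, Clustal and Stockholm parsing is delegated to Biopython's SeqIO /
AlignIO; this module wraps them with the strict validation the estimators
rely on (non-empty ids, duplicate rejection, equal-length alignment rows)
and adds the dot-bracket codec, which has no Biopython equivalent.

All coordinates in every format handled here are 0-based; the probability-
matrix TSV dialect lives in :mod:`gcentroid.matrices`, Newick handling in
:mod:`gcentroid.phylo`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fold import SecondaryStructure

__all__ = [
    "SequenceRecord",
    "MultipleAlignment",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "structure_to_dotbracket",
    "dotbracket_to_structure",
]

GAP_CHARS = "-."


@dataclass(frozen=True)
class SequenceRecord:
    """A named, uppercased sequence."""

    id: str
    residues: str
    alphabet: str = "rna"

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record needs a non-empty id")
        if not self.residues:
            raise ValueError(f"sequence record {self.id!r} is empty")


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows plus the column -> sequence-position map."""

    ids: list
    rows: list
    column_map: list = field(default_factory=list)

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(f"row {rid!r} has ragged length {len(row)}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids")
        if not self.column_map:
            self.column_map = []
            for row in self.rows:
                cmap, pos = [], 0
                for ch in row:
                    if ch in GAP_CHARS:
                        cmap.append(None)
                    else:
                        cmap.append(pos)
                        pos += 1
                self.column_map.append(cmap)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def degapped(self, r: int) -> str:
        return "".join(ch for ch in self.rows[r] if ch not in GAP_CHARS)

    def position(self, r: int, col: int):
        """Sequence position of row r at column col, or None on a gap."""
        return self.column_map[r][col]


def read_fasta(path, alphabet: str = "rna") -> list:
    """Records in file order, uppercased, with duplicate ids rejected."""
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper(), alphabet)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate FASTA ids")
    return records


def write_fasta(records, path):
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def read_alignment(path, dialect: str = "clustal") -> MultipleAlignment:
    """Clustal or Stockholm alignment; per-file markup is ignored."""
    if dialect not in ("clustal", "stockholm"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    aln = AlignIO.read(str(path), dialect)
    return MultipleAlignment(
        ids=[rec.id for rec in aln],
        rows=[str(rec.seq).upper() for rec in aln],
    )


def write_alignment(aln: MultipleAlignment, path, dialect: str = "clustal"):
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=rid, description="") for rid, row in zip(aln.ids, aln.rows)]
    )
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, dialect)


def structure_to_dotbracket(structure: SecondaryStructure) -> str:
    return structure.dotbracket()


def dotbracket_to_structure(text: str) -> SecondaryStructure:
    """Parse a balanced dot-bracket string; errors carry the position."""
    stack, pairs = [], []
    for pos, ch in enumerate(text):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(frozenset(pairs), len(text))
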