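"""Aligned-FASTA and gap-character-matrix I/O.

FASTA reading upper-cases sequences and accepts only {A,C,G,T,-}; the gap
character matrix is written as a relaxed PHYLIP-style 0/1 block preceded by
a ``#sites:`` provenance line giving the 0-based source column of each coded
character.
"""

from __future__ import annotations

import os
from typing import List, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import Alignment, GapCharacterMatrix

__all__ = [
    "read_alignment_fasta",
    "write_alignment_fasta",
    "write_gap_matrix",
    "read_gap_matrix",
]

PathLike = Union[str, os.PathLike]


def read_alignment_fasta(path: PathLike) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    taxa = tuple(r.id for r in records)
    rows = tuple(str(r.seq).upper() for r in records)
    return Alignment(taxa, rows)


def write_alignment_fasta(alignment: Alignment, path: PathLike) -> None:
    records = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(alignment.taxa, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gap_matrix(matrix: GapCharacterMatrix, handle_or_path) -> None:
    own = isinstance(handle_or_path, (str, os.PathLike))
    fh: TextIO = open(handle_or_path, "w") if own else handle_or_path
    try:
        fh.write(f"{len(matrix.taxa)} {matrix.n_characters}\n")
        fh.write("#sites: " + " ".join(map(str, matrix.site_index)) + "\n")
        width = max((len(t) for t in matrix.taxa), default=0) + 2
        for taxon, row in zip(matrix.taxa, matrix.characters):
            fh.write(taxon.ljust(width) + "".join(map(str, row)) + "\n")
    finally:
        if own:
            fh.close()


def read_gap_matrix(path: PathLike) -> GapCharacterMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        n_taxa, n_chars = int(header[0]), int(header[1])
        sites_line = fh.readline()
        if not sites_line.startswith("#sites:"):
            raise ValueError("missing '#sites:' provenance line")
        sites = tuple(int(x) for x in sites_line.split()[1:])
        taxa: List[str] = []
        chars: List[tuple] = []
        for _ in range(n_taxa):
            name, block = fh.readline().split()
            if len(block) != n_chars:
                raise ValueError(f"row {name!r} has {len(block)} characters, expected {n_chars}")
            taxa.append(name)
            chars.append(tuple(int(c) for c in block))
    return GapCharacterMatrix(tuple(taxa), tuple(chars), sites)
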