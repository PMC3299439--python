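"""Gapped DNA alignments over {A,C,G,T,-} and gap coding.

The gap symbol is '-' only.  Ambiguity codes ('N', '?', IUPAC letters) are
rejected rather than silently treated as missing: the analyses here are about
indel gaps specifically, and conflating them with ambiguous base calls would
change the question being asked.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "ALPHABET",
    "GAP",
    "Alignment",
    "GapTreatment",
    "GapCharacterMatrix",
    "strip_gapped_sites",
    "is_monotypic",
    "gap_code",
]

NUCS = "ACGT"
GAP = "-"
ALPHABET = NUCS + GAP

# integer codes used by the likelihood machinery; 4 = gap/missing
CODE: Dict[str, int] = {c: i for i, c in enumerate(ALPHABET)}


class GapTreatment(enum.Enum):
    """How a likelihood (or downstream) analysis handles gap characters."""

    MISSING_DATA = "missing"          # marginalise a gapped leaf over {A,C,G,T}
    STRIP_GAPPED_SITES = "strip"      # drop every column containing any gap
    GAP_CODE = "gapcode"              # recode gapped columns as binary characters


@dataclass(frozen=True)
class Alignment:
    """An aligned matrix of characters over {A,C,G,T,-}, taxa × R sites."""

    taxa: Tuple[str, ...]
    rows: Tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        for taxon, row in zip(self.taxa, self.rows):
            bad = set(row) - set(ALPHABET)
            if bad:
                raise ValueError(
                    f"row {taxon!r} contains characters outside ACGT-: {sorted(bad)} "
                    "(ambiguity codes such as 'N'/'?' are not accepted)"
                )

    @classmethod
    def from_dict(cls, seqs: Dict[str, str]) -> "Alignment":
        taxa = tuple(seqs)
        return cls(taxa, tuple(seqs[t].upper() for t in taxa))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        """R, the number of columns."""
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, i: int) -> Dict[str, str]:
        """Site i as a taxon -> character mapping (0-based)."""
        return {t: r[i] for t, r in zip(self.taxa, self.rows)}

    def columns(self) -> List[str]:
        return ["".join(r[i] for r in self.rows) for i in range(self.n_sites)]

    def codes(self) -> np.ndarray:
        """(n_taxa, R) int8 matrix; A..T -> 0..3, '-' -> 4."""
        out = np.empty((self.n_taxa, self.n_sites), dtype=np.int8)
        for j, row in enumerate(self.rows):
            out[j] = [CODE[c] for c in row]
        return out

    def take_sites(self, idx: Sequence[int]) -> "Alignment":
        return Alignment(
            self.taxa, tuple("".join(r[i] for i in idx) for r in self.rows)
        )


@dataclass(frozen=True)
class GapCharacterMatrix:
    """Binary presence/absence characters coded from gap-containing columns.

    ``characters[t][k]`` is 1 where taxon t has a nucleotide in the k-th coded
    column, 0 where it has a gap.  ``site_index`` records, per character, the
    0-based column of the source alignment it was coded from.
    """

    taxa: Tuple[str, ...]
    characters: Tuple[Tuple[int, ...], ...]  # taxa × K
    site_index: Tuple[int, ...] = field(default=())

    def __post_init__(self):
        for row in self.characters:
            if len(row) != self.n_characters:
                raise ValueError("ragged character matrix")
            if set(row) - {0, 1}:
                raise ValueError("characters must be binary")

    @property
    def n_characters(self) -> int:
        return len(self.characters[0]) if self.characters else 0

    def character(self, k: int) -> Dict[str, int]:
        return {t: self.characters[j][k] for j, t in enumerate(self.taxa)}

    def presence_set(self, k: int) -> frozenset:
        return frozenset(
            t for j, t in enumerate(self.taxa) if self.characters[j][k] == 1
        )


def strip_gapped_sites(alignment: Alignment) -> Alignment:
    """Drop every column containing at least one gap (may leave R = 0)."""
    keep = [
        i
        for i in range(alignment.n_sites)
        if GAP not in (r[i] for r in alignment.rows)
    ]
    return alignment.take_sites(keep)


def is_monotypic(alignment: Alignment) -> bool:
    """True iff every column's non-gap characters exist and are all one type.

    A fully gapped column disqualifies the alignment, as does any column with
    two different nucleotides.
    """
    for i in range(alignment.n_sites):
        states = {r[i] for r in alignment.rows} - {GAP}
        if len(states) != 1:
            return False
    return True


def gap_code(alignment: Alignment) -> GapCharacterMatrix:
    """One binary presence/absence character per column containing any gap.

    Columns without gaps produce no character.  A fully gapped column yields
    an all-zero character (kept, per the literal coding rule); monotypic
    alignments never contain one.
    """
    cols: List[Tuple[int, ...]] = []
    sites: List[int] = []
    for i in range(alignment.n_sites):
        column = [r[i] for r in alignment.rows]
        if GAP in column:
            cols.append(tuple(0 if c == GAP else 1 for c in column))
            sites.append(i)
    chars = tuple(
        tuple(col[j] for col in cols) for j in range(alignment.n_taxa)
    )
    if not cols:
        chars = tuple(() for _ in alignment.taxa)
    return GapCharacterMatrix(alignment.taxa, chars, tuple(sites))
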