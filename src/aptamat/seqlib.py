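"""RNA aptamer sequences and paired two-point mutant libraries.

Sequences are 5'->3' RNA strings over {A, C, G, U}. Positions are 1-based on
the undecorated body: a 5'-biotin tag and a synthesis spacer never shift the
numbering, so a mutant named ``Seq15_12_35`` refers to positions 12 and 35 of
the original Seq15 body whether or not the molecule carries decorations.

The maturation scheme mutates two positions at once: position ``i`` in a 5'
window (default 10..16) together with its partner ``i + 23`` in a 3' window
(default 33..39). For each paired position all 3 x 3 non-identity base
combinations are enumerated, giving 9 mutants per pair and 63 per parent under
the default 7-pair scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Precedence used to order the two non-complement alternatives of a base.
_BASE_PRECEDENCE = "UGCA"

# Traversal order of (alt1 index, alt2 index) pairs, 1-based, reproducing the
# order in which the nine mutants of a paired position are enumerated:
# the three "diagonal" combinations first, then the two off-diagonal sweeps.
SUBSTITUTION_PATTERN: tuple[tuple[int, int], ...] = (
    (1, 1), (2, 2), (3, 3),
    (1, 2), (2, 3), (3, 2),
    (1, 3), (2, 1), (3, 1),
)


class AlphabetError(ValueError):
    """A character outside {A, C, G, U} was found in an RNA string."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid RNA base {char!r} at position {position} "
            "(alphabet is A, C, G, U)"
        )


class DuplicateNameError(ValueError):
    """Two records in one collection share a name."""


def alternatives(base: str) -> tuple[str, str, str]:
    """The three substitution candidates for ``base``, in canonical order.

    The Watson-Crick complement comes first; the remaining two bases follow in
    U < G < C < A precedence. E.g. A -> (U, G, C) and U -> (A, G, C).
    """
    if base not in RNA_ALPHABET:
        raise AlphabetError(base, 1)
    comp = COMPLEMENT[base]
    rest = [b for b in _BASE_PRECEDENCE if b not in (base, comp)]
    return (comp, rest[0], rest[1])


@dataclass(frozen=True)
class AptamerSequence:
    """A named RNA aptamer, 5'->3', with optional synthesis decorations.

    ``biotin_5p`` and ``spacer`` describe how the molecule is prepared for
    immobilization on a sensor chip; they are metadata and do not enter the
    1-based position numbering of ``bases``.
    """

    name: str
    bases: str
    biotin_5p: bool = False
    spacer: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("bases must be non-empty")
        for label, text in (("bases", self.bases), ("spacer", self.spacer)):
            for i, ch in enumerate(text, start=1):
                if ch not in RNA_ALPHABET:
                    raise AlphabetError(ch, i)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def synthesis_string(self) -> str:
        """Spacer + body, the string actually sent for synthesis."""
        return self.spacer + self.bases

    def base_at(self, position: int) -> str:
        """Base at a 1-based body position."""
        if not 1 <= position <= len(self.bases):
            raise IndexError(
                f"position {position} out of range 1..{len(self.bases)}"
            )
        return self.bases[position - 1]


def parse_rna(name: str, text: str) -> AptamerSequence:
    """Validate and normalize an RNA string into an :class:`AptamerSequence`.

    Whitespace is stripped, lowercase is accepted, and any character outside
    {A, C, G, U} (including DNA's T) raises :class:`AlphabetError` carrying
    the 1-based offending position.
    """
    cleaned = "".join(text.split()).upper()
    if not cleaned:
        raise ValueError(f"empty sequence for {name!r}")
    for i, ch in enumerate(cleaned, start=1):
        if ch not in RNA_ALPHABET:
            raise AlphabetError(ch, i)
    return AptamerSequence(name=name, bases=cleaned)


@dataclass(frozen=True)
class MutationScheme:
    """Paired-window two-point mutation scheme.

    ``window1`` and ``window2`` are inclusive 1-based ranges of equal length;
    position ``i`` in window1 is mutated together with ``i + pairing_offset``
    in window2.
    """

    window1: tuple[int, int] = (10, 16)
    window2: tuple[int, int] = (33, 39)
    pairing_offset: int = 23

    def __post_init__(self) -> None:
        w1_len = self.window1[1] - self.window1[0] + 1
        w2_len = self.window2[1] - self.window2[0] + 1
        if w1_len <= 0 or w2_len <= 0:
            raise ValueError("windows must be non-empty inclusive ranges")
        if w1_len != w2_len:
            raise ValueError("windows must have equal length")
        if self.window2[0] - self.window1[0] != self.pairing_offset:
            raise ValueError(
                "window2 start must be window1 start + pairing_offset"
            )

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        """The (pos1, pos2) position pairs the scheme mutates."""
        return tuple(
            (i, i + self.pairing_offset)
            for i in range(self.window1[0], self.window1[1] + 1)
        )

    def check_fits(self, seq: AptamerSequence) -> None:
        if self.window2[1] > len(seq):
            raise IndexError(
                f"scheme window ends at {self.window2[1]} but {seq.name!r} "
                f"has only {len(seq)} bases"
            )


@dataclass(frozen=True)
class MutantRecord:
    """One two-point mutant derived from a parent aptamer."""

    parent: str
    pos1: int
    pos2: int
    from1: str
    to1: str
    from2: str
    to2: str
    sequence: AptamerSequence
    mutant_name: str

    def __post_init__(self) -> None:
        if self.to1 == self.from1 or self.to2 == self.from2:
            raise ValueError("both positions must actually change")

    @property
    def substitution_labels(self) -> tuple[str, str]:
        """Labels like ('A10U', 'U33A')."""
        return (
            f"{self.from1}{self.pos1}{self.to1}",
            f"{self.from2}{self.pos2}{self.to2}",
        )

    @property
    def unique_label(self) -> str:
        """Unambiguous identifier, e.g. ``Seq1_10U_33A``.

        The field convention ``<parent>_<pos1>_<pos2>`` (see
        :func:`mutant_name`) names all nine substitution variants of a
        position pair identically; this label adds the substituted bases so
        every library member has a distinct id.
        """
        return f"{self.parent}_{self.pos1}{self.to1}_{self.pos2}{self.to2}"


def mutant_name(parent_name: str, pos1: int, pos2: int) -> str:
    """Canonical mutant identifier: ``<parent>_<pos1>_<pos2>``."""
    if pos1 < 1 or pos2 < 1:
        raise ValueError("positions must be positive")
    return f"{parent_name}_{pos1}_{pos2}"


def enumerate_pair_mutants(
    seq: AptamerSequence, pos1: int, pos2: int
) -> list[MutantRecord]:
    """All 9 two-point mutants of ``seq`` at positions ``pos1`` and ``pos2``.

    Every combination of the three non-identity substitutions at each
    position, in the deterministic order given by
    :data:`SUBSTITUTION_PATTERN` over the canonical alternative lists.
    """
    if not 1 <= pos1 < pos2 <= len(seq):
        raise IndexError(
            f"need 1 <= pos1 < pos2 <= {len(seq)}, got ({pos1}, {pos2})"
        )
    from1 = seq.base_at(pos1)
    from2 = seq.base_at(pos2)
    alts1 = alternatives(from1)
    alts2 = alternatives(from2)
    records = []
    for i, j in SUBSTITUTION_PATTERN:
        to1, to2 = alts1[i - 1], alts2[j - 1]
        body = list(seq.bases)
        body[pos1 - 1] = to1
        body[pos2 - 1] = to2
        name = mutant_name(seq.name, pos1, pos2)
        records.append(
            MutantRecord(
                parent=seq.name,
                pos1=pos1,
                pos2=pos2,
                from1=from1,
                to1=to1,
                from2=from2,
                to2=to2,
                sequence=AptamerSequence(name=name, bases="".join(body)),
                mutant_name=name,
            )
        )
    return records


def build_two_point_library(
    seq: AptamerSequence, scheme: MutationScheme | None = None
) -> list[MutantRecord]:
    """Full paired two-point library of ``seq`` under ``scheme``.

    Under the default scheme this is 7 position pairs x 9 substitution
    combinations = 63 mutants, all distinct, each differing from the parent at
    exactly the two paired positions.
    """
    scheme = scheme or MutationScheme()
    scheme.check_fits(seq)
    records: list[MutantRecord] = []
    for pos1, pos2 in scheme.pairs:
        records.extend(enumerate_pair_mutants(seq, pos1, pos2))
    return records


def decorate_for_synthesis(
    seq: AptamerSequence, spacer: str = "AAAAA", biotin: bool = True
) -> AptamerSequence:
    """Attach a 5'-biotin flag and a 5' spacer for chip immobilization.

    The spacer (five adenines by default) gives the immobilized aptamer steric
    accessibility; position numbering still refers to the undecorated body.
    """
    for i, ch in enumerate(spacer, start=1):
        if ch not in RNA_ALPHABET:
            raise AlphabetError(ch, i)
    return replace(seq, biotin_5p=biotin, spacer=spacer)


def strip_decorations(seq: AptamerSequence) -> AptamerSequence:
    """Inverse of :func:`decorate_for_synthesis` on the body."""
    return replace(seq, biotin_5p=False, spacer="")


def read_fasta(path: str | Path) -> list[AptamerSequence]:
    """Read aptamers from a FASTA file; names must be unique."""
    records: list[AptamerSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateNameError(f"duplicate FASTA record name {rec.id!r}")
        seen.add(rec.id)
        records.append(parse_rna(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[AptamerSequence], path: str | Path) -> None:
    """Write aptamer bodies as FASTA (60-column wrap); names must be unique."""
    seqs = list(records)
    names = [s.name for s in seqs]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DuplicateNameError(f"duplicate record names: {dupes}")
    bio = [
        SeqRecord(Seq(s.bases), id=s.name, description="") for s in seqs
    ]
    SeqIO.write(bio, str(path), "fasta")


def library_to_frame(records: Sequence[MutantRecord]) -> pd.DataFrame:
    """Tabulate a mutant library (one row per mutant)."""
    return pd.DataFrame(
        {
            "name": [r.mutant_name for r in records],
            "parent": [r.parent for r in records],
            "pos1": [r.pos1 for r in records],
            "pos2": [r.pos2 for r in records],
            "sub1": [r.substitution_labels[0] for r in records],
            "sub2": [r.substitution_labels[1] for r in records],
            "sequence": [r.sequence.bases for r in records],
        }
    )


def write_library_csv(records: Sequence[MutantRecord], path: str | Path) -> None:
    library_to_frame(records).to_csv(path, index=False)
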