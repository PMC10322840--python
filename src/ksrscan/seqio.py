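"""Reading, writing and translating sequence records.

Sequences are held as plain uppercase strings with a declared alphabet
(protein or DNA).  Gap characters are rejected here on purpose: gapped
sequences only become legal once they are part of an alignment (see
:mod:`ksrscan.compare`).  Positions are 1-based inclusive everywhere in
this package, matching the residue numbering conventions of the kinase
literature (e.g. B-RAF V600).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, List, Literal, Sequence

from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "FastaFormatError",
    "DuplicateIdError",
    "read_fasta",
    "write_fasta",
    "translate",
]

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = set("ACGTN")

Alphabet = Literal["protein", "dna"]


class FastaFormatError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


class DuplicateIdError(ValueError):
    """Two records in one file share an identifier."""


@dataclass(frozen=True)
class SequenceRecord:
    """One identified protein or DNA sequence.

    Attributes
    ----------
    id:
        Accession or label, unique within a collection read from one file.
    description:
        Free text following the id on the FASTA header line.
    residues:
        Uppercase, gap-free sequence string.
    alphabet:
        ``"protein"`` (20 amino acids plus X) or ``"dna"`` (ACGTN).
    """

    id: str
    residues: str
    alphabet: Alphabet = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        object.__setattr__(self, "residues", self.residues.upper())
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"not in the {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]


def read_fasta(path: str | os.PathLike, alphabet: Alphabet = "protein") -> List[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Residues are uppercased on ingest and record order is preserved.
    Raises :class:`FastaFormatError` (naming the line number) on malformed
    headers or illegal characters, and :class:`DuplicateIdError` when two
    headers share an id.  An empty file yields an empty list.
    """
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET
    records: List[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: List[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        name, _, desc = header.partition(" ")
        if not name:
            raise FastaFormatError(f"line {header_line}: empty FASTA header")
        if name in seen:
            raise DuplicateIdError(f"duplicate sequence id {name!r} (line {header_line})")
        seen.add(name)
        residues = "".join(chunks)
        if not residues:
            raise FastaFormatError(f"line {header_line}: record {name!r} has no sequence")
        records.append(SequenceRecord(name, residues, alphabet, desc.strip()))
        header, chunks = None, []

    with open(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                header_line = line_no
            else:
                if header is None:
                    raise FastaFormatError(
                        f"line {line_no}: sequence data before any '>' header"
                    )
                up = line.upper()
                bad = set(up) - allowed
                if bad:
                    raise FastaFormatError(
                        f"line {line_no}: illegal {alphabet} character(s) {sorted(bad)}"
                    )
                chunks.append(up)
        flush(line_no + 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as standard FASTA, ``width`` residues per line."""
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def translate(dna: SequenceRecord, frame: int = 1) -> SequenceRecord:
    """Translate a DNA record with the standard genetic code.

    Translation starts at the ``frame`` offset (1, 2 or 3), stops at the
    first stop codon, and silently drops a trailing partial codon.  Codons
    containing N translate to X.  Stop-codon truncation rather than an
    error is deliberate: printed cloning oligonucleotides encode open
    fragments.
    """
    if dna.alphabet != "dna":
        raise ValueError("translate expects a DNA record")
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    sub = dna.residues[frame - 1 :]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        raise ValueError(f"no complete codon in frame {frame} of {dna.id!r}")
    protein = str(Seq(sub).translate(to_stop=True))
    if not protein:
        raise ValueError(f"{dna.id!r} frame {frame} begins with a stop codon")
    return SequenceRecord(
        id=f"{dna.id}_translated",
        residues=protein,
        alphabet="protein",
        description=f"frame {frame} translation of {dna.id}",
    )
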