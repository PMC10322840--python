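"""Affine-gap pairwise alignment and residue-position liftover.

Global and local protein alignment under the Gotoh three-state affine-gap
model (substitution matrix + gap-open/gap-extend costs), plus bidirectional
1-based position mapping through the alignment columns.  The mapping is the
workhorse for transferring residue coordinates between homologs, e.g.
carrying the B-RAF dimerization arginine (R509) onto the equivalent KSR
position.

The dynamic programming itself is delegated to :class:`Bio.Align.PairwiseAligner`;
this module fixes the scoring conventions (gap of length L costs
``open + (L-1) * extend``, end gaps penalized in global mode) and the
deterministic choice of traceback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

__all__ = [
    "AlignmentParams",
    "PairwiseAlignment",
    "pairwise_align",
    "map_position",
    "percent_identity",
]

Mode = Literal["global", "local"]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for pairwise alignment.

    Defaults are the standard protein choices: BLOSUM62 with gap open 11,
    gap extend 1.  ``gap_open >= gap_extend > 0`` (both entered as positive
    costs).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    mode: Mode = "global"

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend > 0:
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class PairwiseAlignment:
    """An alignment of two sequences as equal-length gapped strings.

    ``columns`` holds, per alignment column, the pair
    ``(position_in_a | None, position_in_b | None)`` with 1-based positions;
    a column is never gap-vs-gap.
    """

    id_a: str
    id_b: str
    gapped_a: str
    gapped_b: str
    score: float
    mode: Mode = "global"
    columns: Tuple[Tuple[Optional[int], Optional[int]], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped strings differ in length")
        if not self.columns:
            object.__setattr__(self, "columns", _build_columns(self.gapped_a, self.gapped_b))
        for ca, cb in zip(self.gapped_a, self.gapped_b):
            if ca == "-" and cb == "-":
                raise ValueError("gap-vs-gap column in alignment")

    def swapped(self) -> "PairwiseAlignment":
        """The same alignment viewed with a and b exchanged."""
        return PairwiseAlignment(
            id_a=self.id_b,
            id_b=self.id_a,
            gapped_a=self.gapped_b,
            gapped_b=self.gapped_a,
            score=self.score,
            mode=self.mode,
            columns=tuple((b, a) for a, b in self.columns),
        )

    def to_tsv(self) -> str:
        """Column map as TSV: col, pos_a, res_a, pos_b, res_b."""
        lines = ["col\tpos_a\tres_a\tpos_b\tres_b"]
        for i, ((pa, pb), ca, cb) in enumerate(
            zip(self.columns, self.gapped_a, self.gapped_b), start=1
        ):
            lines.append(f"{i}\t{pa or '-'}\t{ca}\t{pb or '-'}\t{cb}")
        return "\n".join(lines) + "\n"

    def to_fasta(self) -> str:
        return f">{self.id_a}\n{self.gapped_a}\n>{self.id_b}\n{self.gapped_b}\n"


def _build_columns(gapped_a: str, gapped_b: str) -> Tuple[Tuple[Optional[int], Optional[int]], ...]:
    cols: List[Tuple[Optional[int], Optional[int]]] = []
    pa = pb = 0
    for ca, cb in zip(gapped_a, gapped_b):
        ia = ib = None
        if ca != "-":
            pa += 1
            ia = pa
        if cb != "-":
            pb += 1
            ib = pb
        cols.append((ia, ib))
    return tuple(cols)


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = params.mode
    return aligner


def pairwise_align(
    a: SequenceRecord, b: SequenceRecord, params: AlignmentParams | None = None
) -> PairwiseAlignment:
    """Optimal affine-gap alignment of two protein records.

    Global mode aligns the full sequences (end gaps penalized); local mode
    returns the best-scoring contiguous sub-alignment.  Among co-optimal
    tracebacks the aligner's first enumeration is taken, which is
    deterministic for fixed inputs, so outputs are bit-reproducible.
    """
    params = params or AlignmentParams()
    if a.alphabet != "protein" or b.alphabet != "protein":
        raise ValueError("pairwise_align expects protein records")
    aligner = _make_aligner(params)
    aln = aligner.align(a.residues, b.residues)[0]
    if params.mode == "local":
        ga, gb, columns = _local_columns(aln, a.residues, b.residues)
        return PairwiseAlignment(a.id, b.id, ga, gb, float(aln.score), "local", columns)
    return PairwiseAlignment(a.id, b.id, str(aln[0]), str(aln[1]), float(aln.score), "global")


def _local_columns(aln, seq_a: str, seq_b: str):
    """Gapped strings + 1-based column map for a local alignment."""
    blocks_a, blocks_b = aln.aligned
    ga_parts: List[str] = []
    gb_parts: List[str] = []
    cols: List[Tuple[Optional[int], Optional[int]]] = []
    prev_a = prev_b = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            for i in range(prev_a, a0):  # unaligned a residues between blocks
                ga_parts.append(seq_a[i])
                gb_parts.append("-")
                cols.append((i + 1, None))
            for j in range(prev_b, b0):
                ga_parts.append("-")
                gb_parts.append(seq_b[j])
                cols.append((None, j + 1))
        for i, j in zip(range(a0, a1), range(b0, b1)):
            ga_parts.append(seq_a[i])
            gb_parts.append(seq_b[j])
            cols.append((i + 1, j + 1))
        prev_a, prev_b = a1, b1
    return "".join(ga_parts), "".join(gb_parts), tuple(cols)


def map_position(aln: PairwiseAlignment, pos: int) -> Optional[int]:
    """Map a 1-based position in sequence a to its column partner in b.

    Returns ``None`` when the column has a gap in b (no homologous
    residue).  Raises :class:`IndexError` when ``pos`` is outside the
    positions of a covered by the alignment.
    """
    a_positions = [pa for pa, _ in aln.columns if pa is not None]
    if not a_positions or not a_positions[0] <= pos <= a_positions[-1]:
        span = f"{a_positions[0]}..{a_positions[-1]}" if a_positions else "(empty)"
        raise IndexError(f"position {pos} outside aligned span {span} of {aln.id_a}")
    for pa, pb in aln.columns:
        if pa == pos:
            return pb
    raise IndexError(f"position {pos} not present in alignment of {aln.id_a}")


def percent_identity(aln: PairwiseAlignment) -> float:
    """Identical columns over columns where both sequences have residues."""
    both = ident = 0
    for (pa, pb), ca, cb in zip(aln.columns, aln.gapped_a, aln.gapped_b):
        if pa is not None and pb is not None:
            both += 1
            if ca == cb:
                ident += 1
    if both == 0:
        raise ValueError("alignment has no residue-residue columns; identity undefined")
    return ident / both
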