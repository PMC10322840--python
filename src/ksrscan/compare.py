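"""Comparative computations: divergence profiling, donor-specific residue
detection and cross-homolog mutation transposition.

These are the analyses that turn a KSR3/RAF alignment into predictions:

* :func:`divergence_profile` — per-reference-position fraction of a
  sequence set differing from the reference (the histogram style of
  analysis that shows KSR3 divergence from B-RAF concentrating in the
  P-loop, alphaC helix, dimerization interface, catalytic loop and
  activation segment);
* :func:`donor_specific_residues` — alignment columns where a conserved
  donor-family residue differs from the acceptor (KSR3-specific residues
  absent from RAF);
* :func:`transpose_mutations` — turns donor-specific residues into
  candidate acceptor mutations (substitutions, deletions where the
  acceptor aligns to donor gaps, segment swaps for runs), in standard
  protein-mutation notation (L485R, p.Leu485Arg);
* :func:`known_oncogenic_lookup` — flags candidates against an embedded
  static list of B-RAF cancer-mutation positions/variants; no external
  database is queried.

A :class:`LandmarkTable` guards against numbering drift by validating
that cited residue letters really sit at their stated coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import AlignIO

from .motifs import KinaseAnnotation
from .seqio import PROTEIN_ALPHABET, SequenceRecord

__all__ = [
    "MultipleAlignment",
    "DivergenceProfile",
    "CandidateMutation",
    "LandmarkTable",
    "read_msa",
    "divergence_profile",
    "region_summary",
    "donor_specific_residues",
    "transpose_mutations",
    "known_oncogenic_lookup",
    "load_landmark_table",
    "validate_landmarks",
    "AA3",
]

AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr", "X": "Xaa",
}


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows over an ordered id list."""

    ids: Tuple[str, ...]
    rows: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("ragged alignment rows")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - PROTEIN_ALPHABET - {"-"}
            if bad:
                raise ValueError(f"row {rid!r} contains illegal characters {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise KeyError(f"id {rid!r} not in alignment") from None

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")

    def drop_all_gap_columns(self) -> Tuple["MultipleAlignment", int]:
        arr = np.array([list(r) for r in self.rows])
        keep = ~(arr == "-").all(axis=0)
        dropped = int((~keep).sum())
        rows = tuple("".join(row) for row in arr[:, keep])
        return MultipleAlignment(self.ids, rows), dropped


def read_msa(path, fmt: Literal["fasta", "clustal"] = "fasta") -> MultipleAlignment:
    """Read an aligned-FASTA or Clustal MSA; all-gap columns are dropped."""
    aln = AlignIO.read(path, fmt)
    msa = MultipleAlignment(
        tuple(rec.id for rec in aln),
        tuple(str(rec.seq).upper() for rec in aln),
    )
    normalized, _ = msa.drop_all_gap_columns()
    return normalized


# ---------------------------------------------------------------------------
# divergence profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivergenceProfile:
    """Fraction of a sequence set differing from the reference, per
    reference position (reference-gap columns skipped)."""

    reference_id: str
    positions: Tuple[int, ...]
    residues: Tuple[str, ...]
    fractions: Tuple[float, ...]
    n_compared: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "ref_residue": self.residues,
             "fraction": self.fractions, "n": self.n_compared}
        )


def divergence_profile(
    msa: MultipleAlignment,
    ref_id: str,
    set_ids: Sequence[str],
    gaps_divergent: bool = True,
) -> DivergenceProfile:
    """Per-reference-position divergence of ``set_ids`` from ``ref_id``.

    For each column where the reference has a residue, the fraction of set
    sequences whose symbol differs from the reference's; a gap in a set
    sequence counts as divergent (switchable).  Columns where the
    reference is gapped are skipped.
    """
    if not set_ids:
        raise ValueError("empty comparison set")
    ref_row = msa.row(ref_id)
    set_rows = [msa.row(s) for s in set_ids]
    positions: List[int] = []
    residues: List[str] = []
    fractions: List[float] = []
    pos = 0
    for col, ref_ch in enumerate(ref_row):
        if ref_ch == "-":
            continue
        pos += 1
        divergent = compared = 0
        for row in set_rows:
            ch = row[col]
            if ch == "-":
                if gaps_divergent:
                    divergent += 1
                    compared += 1
                continue
            compared += 1
            if ch != ref_ch:
                divergent += 1
        positions.append(pos)
        residues.append(ref_ch)
        fractions.append(divergent / compared if compared else 0.0)
    return DivergenceProfile(ref_id, tuple(positions), tuple(residues),
                             tuple(fractions), len(set_rows))


def region_summary(
    profile: DivergenceProfile, ref_annotation: KinaseAnnotation
) -> pd.DataFrame:
    """Mean divergence per named region of the reference, ranked.

    Regions with zero reference positions are omitted.
    """
    frac = dict(zip(profile.positions, profile.fractions))
    records = []
    for name, (a, b) in ref_annotation.regions.items():
        vals = [frac[p] for p in range(a, b + 1) if p in frac]
        if not vals:
            continue
        records.append({"region": name, "start": a, "end": b,
                        "mean_divergence": float(np.mean(vals)), "n_positions": len(vals)})
    df = pd.DataFrame.from_records(records)
    df = df.sort_values("mean_divergence", ascending=False, kind="mergesort")
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# donor-specific residues and transposition
# ---------------------------------------------------------------------------

def donor_specific_residues(
    msa: MultipleAlignment,
    donor_ids: Sequence[str],
    acceptor_ref_id: str,
    conservation: float = 0.8,
) -> List[Tuple[int, str, str]]:
    """Acceptor positions where a conserved donor residue differs.

    Returns ``(acceptor_position, acceptor_residue, donor_consensus)`` for
    every column in which at least ``conservation`` of the donors share one
    residue and that residue differs from the acceptor's.
    """
    if not donor_ids:
        raise ValueError("empty donor set")
    acc_row = msa.row(acceptor_ref_id)
    donor_rows = [msa.row(d) for d in donor_ids]
    out: List[Tuple[int, str, str]] = []
    pos = 0
    for col, acc_ch in enumerate(acc_row):
        if acc_ch == "-":
            continue
        pos += 1
        column = [row[col] for row in donor_rows]
        best_res, best_n = None, 0
        for res in set(column) - {"-"}:
            n = column.count(res)
            if n > best_n or (n == best_n and best_res and res < best_res):
                best_res, best_n = res, n
        if best_res is None:
            continue
        if best_n / len(column) >= conservation and best_res != acc_ch:
            out.append((pos, acc_ch, best_res))
    return out


def donor_gap_runs(
    msa: MultipleAlignment,
    donor_ids: Sequence[str],
    acceptor_ref_id: str,
    conservation: float = 0.8,
) -> List[Tuple[int, str]]:
    """Maximal runs of acceptor positions aligned to gaps in (a conserved
    majority of) the donors; returns (start position, deleted residues)."""
    acc_row = msa.row(acceptor_ref_id)
    donor_rows = [msa.row(d) for d in donor_ids]
    gap_positions: List[int] = []
    pos = 0
    residue_at: Dict[int, str] = {}
    for col, acc_ch in enumerate(acc_row):
        if acc_ch == "-":
            continue
        pos += 1
        residue_at[pos] = acc_ch
        column = [row[col] for row in donor_rows]
        if column.count("-") / len(column) >= conservation:
            gap_positions.append(pos)
    runs: List[Tuple[int, str]] = []
    for p in gap_positions:
        if runs and p == runs[-1][0] + len(runs[-1][1]):
            runs[-1] = (runs[-1][0], runs[-1][1] + residue_at[p])
        else:
            runs.append((p, residue_at[p]))
    return runs


@dataclass(frozen=True)
class CandidateMutation:
    """A donor-specific residue (or run) transposed onto the acceptor."""

    acceptor_id: str
    acceptor_position: int
    acceptor_residue: str  # one residue, or the full run for del/swap
    payload: str  # donor residue(s); empty for a deletion
    kind: Literal["substitution", "deletion", "segment_swap"]
    region: str
    donor_id: str
    donor_position: Optional[int]
    known_oncogenic: Optional[bool] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind == "substitution" and self.payload == self.acceptor_residue:
            raise ValueError("substitution donor residue equals acceptor residue")

    @property
    def label(self) -> str:
        a, p = self.acceptor_residue, self.acceptor_position
        if self.kind == "substitution":
            return f"{a}{p}{self.payload}"
        if self.kind == "deletion":
            end = p + len(a) - 1
            return f"del{a[0]}{p}" + (f"_{a[-1]}{end}" if len(a) > 1 else "")
        return f"{a}{p}>{self.payload}"

    @property
    def hgvs(self) -> str:
        p = self.acceptor_position
        if self.kind == "substitution":
            return f"p.{AA3[self.acceptor_residue]}{p}{AA3[self.payload]}"
        if self.kind == "deletion":
            end = p + len(self.acceptor_residue) - 1
            if len(self.acceptor_residue) == 1:
                return f"p.{AA3[self.acceptor_residue]}{p}del"
            return f"p.{AA3[self.acceptor_residue[0]]}{p}_{AA3[self.acceptor_residue[-1]]}{end}del"
        end = p + len(self.acceptor_residue) - 1
        ins = "".join(AA3[c] for c in self.payload)
        return f"p.{AA3[self.acceptor_residue[0]]}{p}_{AA3[self.acceptor_residue[-1]]}{end}delins{ins}"


DEFAULT_TRANSPOSE_REGIONS = (
    "BETA3", "BETA3_ALPHAC_LOOP", "ALPHAC", "DIF", "BETA7_BETA8", "AS",
)


def transpose_mutations(
    msa: MultipleAlignment,
    donor_ids: Sequence[str],
    acceptor: SequenceRecord,
    acceptor_annotation: KinaseAnnotation,
    conservation: float = 0.8,
    regions: Sequence[str] = DEFAULT_TRANSPOSE_REGIONS,
    min_swap_run: int = 3,
) -> List[CandidateMutation]:
    """Candidate acceptor mutations from donor-specific residues.

    Within the regions of interest (by default beta3 through the
    activation segment; the P-loop is excluded), isolated donor-specific
    residues become substitutions, contiguous runs of at least
    ``min_swap_run`` become a single segment swap carrying the donor
    consensus, and acceptor residues aligned to donor gaps become one
    deletion candidate per contiguous run.
    """
    if acceptor.id not in msa.ids:
        raise ValueError(f"acceptor {acceptor.id!r} not in alignment")
    if msa.ungapped(acceptor.id) != acceptor.residues:
        raise ValueError("acceptor row does not ungap to the acceptor sequence")

    spans = {r: acceptor_annotation.regions[r]
             for r in regions if r in acceptor_annotation.regions}

    def region_of(pos: int) -> Optional[str]:
        for name, (a, b) in spans.items():
            if a <= pos <= b:
                return name
        return None

    donor_tag = "+".join(donor_ids) if len(donor_ids) <= 3 else f"{len(donor_ids)}_donors"
    hits = donor_specific_residues(msa, donor_ids, acceptor.id, conservation)
    in_scope = [(p, a, d) for p, a, d in hits if region_of(p)]

    candidates: List[CandidateMutation] = []
    run: List[Tuple[int, str, str]] = []

    def flush_run() -> None:
        if not run:
            return
        if len(run) >= min_swap_run:
            start = run[0][0]
            acc = "".join(a for _, a, _ in run)
            pay = "".join(d for _, _, d in run)
            note = ""
            if acc == "QLQA":
                note = ("alphaC QLQA segment; donor consensus recorded verbatim "
                        "(text DIND vs primer DLND discrepancy noted)")
            candidates.append(CandidateMutation(
                acceptor.id, start, acc, pay, "segment_swap",
                region_of(start) or "", donor_tag, None, note=note))
        else:
            for p, a, d in run:
                candidates.append(CandidateMutation(
                    acceptor.id, p, a, d, "substitution",
                    region_of(p) or "", donor_tag, _donor_position(msa, donor_ids[0], acceptor.id, p)))
        run.clear()

    for p, a, d in in_scope:
        if run and p == run[-1][0] + 1:
            run.append((p, a, d))
        else:
            flush_run()
            run.append((p, a, d))
    flush_run()

    for start, deleted in donor_gap_runs(msa, donor_ids, acceptor.id, conservation):
        reg = region_of(start)
        if reg:
            candidates.append(CandidateMutation(
                acceptor.id, start, deleted, "", "deletion", reg, donor_tag, None))

    candidates.sort(key=lambda c: c.acceptor_position)
    return candidates


def _donor_position(
    msa: MultipleAlignment, donor_id: str, acceptor_id: str, acceptor_pos: int
) -> Optional[int]:
    acc_row, don_row = msa.row(acceptor_id), msa.row(donor_id)
    pa = pd_ = 0
    for ca, cd in zip(acc_row, don_row):
        if cd != "-":
            pd_ += 1
        if ca != "-":
            pa += 1
            if pa == acceptor_pos:
                return pd_ if cd != "-" else None
    return None


# ---------------------------------------------------------------------------
# known-oncogenic lookup (embedded static list; no external queries)
# ---------------------------------------------------------------------------

# B-RAF cancer-mutation positions with, where stated, the specific variants
# reported; None means any substitution at the position is in the list.
KNOWN_ONCOGENIC_BRAF: Dict[int, Optional[set]] = {
    464: {"E", "V", "R"},
    468: {"K", "R", "N", "Q", "D"},
    469: {"A", "V", "S"},
    485: {"F", "W", "S"},
    499: None,
    506: None,
    588: None,
    594: {"G"},
    597: {"H", "T", "G", "N", "M", "F", "V"},
    600: {"E"},
}
# variants explicitly reported as never described
NOVEL_BRAF_VARIANTS = {(485, "R"), (506, "E")}

BRAF_ACCEPTOR_IDS = {"BRAF", "BRAF_HS", "P15056", "hBRAF", "BRAF_REF"}


def known_oncogenic_lookup(c: CandidateMutation) -> Tuple[Optional[bool], str]:
    """Flag a candidate against the embedded B-RAF cancer-mutation list.

    Returns ``(flag, note)``; the flag is ``None`` (undetermined) for
    non-B-RAF acceptors.  Variant-specific entries are honoured: L485F is
    flagged while L485R — reported as never described — is not.
    """
    if c.acceptor_id not in BRAF_ACCEPTOR_IDS:
        return None, "acceptor is not the packaged human B-RAF reference"
    if c.kind != "substitution":
        return False, "position list covers substitutions only"
    pos, var = c.acceptor_position, c.payload
    if (pos, var) in NOVEL_BRAF_VARIANTS:
        return False, f"{c.label}: not previously described"
    variants = KNOWN_ONCOGENIC_BRAF.get(pos, False)
    if variants is False:
        return False, f"position {pos} not in the cancer-mutation list"
    if variants is None or var in variants:
        return True, f"cancer mutations reported at B-RAF {pos}"
    return False, (f"cancer mutations at B-RAF {pos} are "
                   f"{'/'.join(sorted(variants))}, not {var}")


def annotate_candidates(candidates: Iterable[CandidateMutation]) -> List[CandidateMutation]:
    """Return candidates with the oncogenic flag and note filled in."""
    out = []
    for c in candidates:
        flag, note = known_oncogenic_lookup(c)
        merged = f"{c.note}; {note}" if c.note else note
        out.append(CandidateMutation(
            c.acceptor_id, c.acceptor_position, c.acceptor_residue, c.payload,
            c.kind, c.region, c.donor_id, c.donor_position, flag, merged))
    return out


def candidates_to_frame(candidates: Sequence[CandidateMutation]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"label": c.label, "hgvs": c.hgvs, "kind": c.kind, "region": c.region,
          "acceptor": c.acceptor_id, "position": c.acceptor_position,
          "wildtype": c.acceptor_residue, "donor_residue": c.payload,
          "donor": c.donor_id, "donor_position": c.donor_position,
          "known_oncogenic": c.known_oncogenic, "note": c.note}
         for c in candidates]
    )


# ---------------------------------------------------------------------------
# landmark table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkTable:
    """Named residue coordinates per sequence, with a numbering offset."""

    entries: Tuple[Tuple[str, str, int, str], ...]  # (seq id, name, pos, residue)
    offset: int = 0

    def for_sequence(self, seq_id: str) -> List[Tuple[str, int, str]]:
        return [(n, p, r) for s, n, p, r in self.entries if s == seq_id]


def load_landmark_table(offset: int = 0) -> LandmarkTable:
    """The packaged landmark table for the synthetic reference set."""
    path = resources.files("ksrscan.data") / "landmarks_synthetic.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    entries = tuple(
        (row.sequence_id, row.landmark, int(row.position), row.residue)
        for row in df.itertuples()
    )
    return LandmarkTable(entries, offset)


def validate_landmarks(
    table: LandmarkTable, records: Dict[str, SequenceRecord]
) -> pd.DataFrame:
    """Per-landmark residue-identity check with offset diagnosis.

    Reports pass/fail per landmark; when a uniform shift would fix every
    failure of one sequence, that shift is suggested as
    ``suggested_offset``.
    """
    rows = []
    for seq_id, rec in records.items():
        marks = table.for_sequence(seq_id)
        if not marks:
            continue
        results = []
        for name, pos, residue in marks:
            p = pos + table.offset
            actual = rec.residues[p - 1] if 1 <= p <= len(rec.residues) else None
            results.append((name, pos, residue, actual, actual == residue))
        n_fail = sum(1 for r in results if not r[4])
        suggestion = None
        if n_fail > 0:
            for shift in range(-50, 51):
                if shift == 0:
                    continue
                if all(
                    1 <= pos + table.offset + shift <= len(rec.residues)
                    and rec.residues[pos + table.offset + shift - 1] == residue
                    for name, pos, residue in marks
                ):
                    suggestion = shift
                    break
        for name, pos, residue, actual, ok in results:
            rows.append({"sequence_id": seq_id, "landmark": name, "position": pos,
                         "expected": residue, "actual": actual, "ok": ok,
                         "suggested_offset": suggestion})
    return pd.DataFrame(rows)
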