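"""Kinase-domain motif location, grading and architecture fingerprinting.

The annotator inventories the motifs that distinguish catalytically
competent RAF kinases from KSR pseudokinases:

* the glycine-rich P-loop (G-X-G-X-X-G) of the ATP-binding site,
* the VAIK motif whose lysine positions ATP for phosphotransfer,
* the HRD motif of the catalytic loop (catalytic aspartate),
* the DFG motif at the start of the activation segment,
* the basic RKTR motif at the C-terminal end of the alphaC helix
  (dimerization interface),
* the acidic NtA motif just N-terminal of the kinase domain,
* the N- and C-terminal 14-3-3 binding serines,
* the C1/CRD zinc-finger cysteine pattern,
* ERK feedback phosphorylation sites (P-X-[ST]-P) outside the kinase
  domain,

and the CC-SAM and RBD accessory domains (by local alignment against
packaged exemplars).  Each motif is graded canonical / degenerate /
absent: a motif is *degenerate* when the best window-constrained match
still retains at least half of its anchor residues (for the dimerization
motif: when the key arginine survives, so that neutral variants such as
SMIR/SKIR are recognised), and *absent* otherwise.

Search windows are defined relative to the kinase-domain anchor rather
than absolute coordinates.  Anchoring prefers canonical motif hits with
priority HRD > DFG > VAIK > P-loop; when no canonical anchor exists (as
in KSR3, where the catalytic motifs are degenerate or missing) the domain
is anchored by local alignment against a packaged canonical kinase-domain
exemplar, and as a last resort the whole sequence is used with a
low-confidence flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Literal, Optional, Sequence, Tuple

from .align import AlignmentParams, pairwise_align
from .seqio import SequenceRecord, read_fasta

__all__ = [
    "MotifDef",
    "MotifHit",
    "KinaseAnnotation",
    "DEFAULT_CATALOG",
    "load_exemplars",
    "locate_kinase_domain",
    "scan_motif",
    "locate_nta",
    "locate_cterm_1433",
    "locate_nterm_1433",
    "locate_c1_crd",
    "detect_domain_by_exemplar",
    "count_erk_feedback_sites",
    "annotate",
]

Status = Literal["canonical", "degenerate", "absent"]

# offsets of motif starts relative to the P-loop start (the domain origin),
# taken from the canonical kinase-domain geometry of the packaged exemplar
MOTIF_OFFSETS = {"PLOOP": 0, "VAIK": 16, "DIMER_RKTR": 42, "HRD": 110, "DFG": 130}
AS_LENGTH = 30  # activation segment: DFG through DFG+30
DOMAIN_END_OFFSET = 160 + AS_LENGTH  # ~30 residues past the AS end


@dataclass(frozen=True)
class MotifDef:
    """A degenerate motif pattern with its anchors and search window.

    ``pattern`` is a tuple of allowed-residue strings, one per position
    (empty string = any residue).  ``anchors`` are the pattern positions
    whose residues carry the motif's identity; a window-constrained best
    match keeping at least ``min_retained`` of them (and the key residue,
    when ``require_key``) is graded degenerate.
    """

    motif_id: str
    pattern: Tuple[str, ...]
    exemplar: str
    anchors: Tuple[int, ...]
    key_offset: int
    window_offset: int  # vs the domain origin (P-loop start)
    window_halfwidth: int = 8
    min_retained: int = 0
    require_key: bool = False

    def __post_init__(self) -> None:
        if self.key_offset >= len(self.pattern):
            raise ValueError("key-residue offset beyond pattern length")


DEFAULT_CATALOG: Tuple[MotifDef, ...] = (
    MotifDef("PLOOP", ("G", "", "G", "", "", "G"), "GSGSFG", (0, 2, 5), 0,
             MOTIF_OFFSETS["PLOOP"], min_retained=2),
    MotifDef("VAIK", ("V", "A", "VI", "K"), "VAIK", (0, 1, 2, 3), 3,
             MOTIF_OFFSETS["VAIK"], min_retained=2),
    MotifDef("DIMER_RKTR", ("R", "K", "T", "R"), "RKTR", (0, 1, 2, 3), 3,
             MOTIF_OFFSETS["DIMER_RKTR"], min_retained=1, require_key=True),
    MotifDef("HRD", ("H", "R", "D"), "HRD", (0, 1, 2), 2,
             MOTIF_OFFSETS["HRD"], min_retained=2),
    MotifDef("DFG", ("D", "F", "G"), "DFG", (0, 1, 2), 0,
             MOTIF_OFFSETS["DFG"], min_retained=2),
)
_CATALOG_BY_ID = {d.motif_id: d for d in DEFAULT_CATALOG}


@dataclass(frozen=True)
class MotifHit:
    """Result of scanning one motif in one sequence (1-based, inclusive)."""

    motif_id: str
    status: Status
    start: Optional[int] = None
    end: Optional[int] = None
    matched: str = ""
    key_position: Optional[int] = None
    variant: str = ""

    def __post_init__(self) -> None:
        if self.status != "absent":
            if self.start is None or self.end is None or self.start > self.end:
                raise ValueError(f"{self.motif_id}: hit without a valid span")
            if self.key_position is not None and not (
                self.start <= self.key_position <= self.end
            ):
                raise ValueError(f"{self.motif_id}: key residue outside span")


@dataclass
class KinaseAnnotation:
    """Per-sequence motif inventory, region table and fingerprint."""

    sequence_id: str
    kinase_domain: Tuple[int, int]
    low_confidence: bool
    anchor: str  # which evidence anchored the domain
    hits: Dict[str, MotifHit]
    regions: Dict[str, Tuple[int, int]]
    fingerprint: Dict[str, object]

    def to_tsv(self) -> str:
        lines = ["motif\tstatus\tstart\tend\tmatched\tkey_position\tvariant"]
        for mid, h in self.hits.items():
            lines.append(
                f"{mid}\t{h.status}\t{h.start or ''}\t{h.end or ''}\t"
                f"{h.matched}\t{h.key_position or ''}\t{h.variant}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# exemplars
# ---------------------------------------------------------------------------

def load_exemplars() -> Dict[str, SequenceRecord]:
    """Packaged synthetic CC-SAM / RBD / kinase-domain exemplars."""
    path = resources.files("ksrscan.data") / "exemplars_synthetic.fasta"
    with resources.as_file(path) as p:
        records = read_fasta(p, "protein")
    return {r.id: r for r in records}


# ---------------------------------------------------------------------------
# domain anchoring
# ---------------------------------------------------------------------------

_ANCHOR_PRIORITY = ("HRD", "DFG", "VAIK", "PLOOP")
_ANCHOR_REGEX = {
    "HRD": re.compile("(?=HRD)"),
    "DFG": re.compile("(?=DFG)"),
    "VAIK": re.compile("(?=VA[VI]K)"),
    "PLOOP": re.compile("(?=G.G..G)"),
}


def locate_kinase_domain(
    seq: SequenceRecord,
    exemplar: Optional[SequenceRecord] = None,
) -> Tuple[Tuple[int, int], bool, str, int]:
    """Bracket the kinase domain.

    Returns ``(span, low_confidence, anchor, origin)`` where ``origin`` is
    the estimated 1-based P-loop start position the motif windows hang off.
    Canonical motif anchors are preferred (priority HRD > DFG > VAIK >
    P-loop, mutually consistent anchors outvoting lone ones); a sequence
    with no canonical anchor is anchored by local alignment against the
    canonical kinase-domain exemplar; failing that the whole sequence is
    returned with a low-confidence flag.
    """
    s = seq.residues
    candidates: List[Tuple[str, int]] = []  # (anchor type, origin estimate)
    for name in _ANCHOR_PRIORITY:
        for m in _ANCHOR_REGEX[name].finditer(s):
            candidates.append((name, m.start() + 1 - MOTIF_OFFSETS[name]))

    if candidates:
        # score each candidate origin by how many anchor types agree (+-10)
        weight = {n: w for w, n in enumerate(reversed(_ANCHOR_PRIORITY), start=1)}
        best = max(
            candidates,
            key=lambda c: (
                sum(weight[n2] for n2, o2 in candidates if abs(o2 - c[1]) <= 10),
                weight[c[0]],
                -c[1],
            ),
        )
        origin = best[1]
        span = (max(1, origin - 7), min(len(s), origin + DOMAIN_END_OFFSET))
        return span, False, best[0], origin

    if exemplar is None:
        exemplar = load_exemplars()["KINASE_DOMAIN_EXEMPLAR"]
    aln = pairwise_align(exemplar, seq, AlignmentParams(mode="local"))
    matched = [(pa, pb) for pa, pb in aln.columns if pa is not None and pb is not None]
    if matched and len(matched) >= 0.3 * len(exemplar.residues):
        pa0, pb0 = matched[0]
        origin = pb0 - (pa0 - 1)
        span = (max(1, origin - 7), min(len(s), origin + DOMAIN_END_OFFSET))
        return span, False, "exemplar", origin

    return (1, len(s)), True, "none", 1


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def _match_score(window_seq: str, mdef: MotifDef, start: int) -> Tuple[int, bool]:
    """(number of anchors matched, all pattern positions satisfied?)."""
    n_anchor = 0
    all_ok = True
    for off, allowed in enumerate(mdef.pattern):
        ch = window_seq[start + off]
        ok = (not allowed) or ch in allowed
        if off in mdef.anchors and ok:
            n_anchor += 1
        if not ok:
            all_ok = False
    return n_anchor, all_ok


def scan_motif(
    seq: SequenceRecord,
    mdef: MotifDef,
    domain: Tuple[int, int],
    origin: Optional[int] = None,
) -> MotifHit:
    """Best match for ``mdef`` inside its window (leftmost wins ties).

    An exact pattern match is canonical; a best match retaining at least
    ``min_retained`` anchors (and the key residue when required) is
    degenerate, with the matched substring reported as the variant;
    otherwise the motif is absent.
    """
    s = seq.residues
    origin = origin if origin is not None else domain[0]
    centre = origin + mdef.window_offset
    lo = max(1, centre - mdef.window_halfwidth)
    hi = min(len(s) - len(mdef.pattern) + 1, centre + mdef.window_halfwidth)
    if hi < lo:
        return MotifHit(mdef.motif_id, "absent")

    # best by key-residue retention (where required), then anchor count,
    # exactness, proximity to the expected site, and finally leftmost — so
    # equally-degenerate spurious matches do not displace the variant at
    # the homologous position
    best = None  # (key_ok, score, exact, -dist, -start)
    key_allowed = mdef.pattern[mdef.key_offset]
    for start in range(lo, hi + 1):
        score, exact = _match_score(s, mdef, start - 1)
        key_ok = (not mdef.require_key) or (
            not key_allowed or s[start - 1 + mdef.key_offset] in key_allowed
        )
        cand = (key_ok, score, exact, -abs(start - centre), -start)
        if best is None or cand > best:
            best = cand
    key_ok, score, exact, start = best[0], best[1], best[2], -best[4]
    end = start + len(mdef.pattern) - 1
    matched = s[start - 1 : end]
    key_pos = start + mdef.key_offset
    if exact:
        return MotifHit(mdef.motif_id, "canonical", start, end, matched, key_pos)
    if score >= mdef.min_retained and key_ok:
        return MotifHit(mdef.motif_id, "degenerate", start, end, matched, key_pos,
                        variant=matched)
    return MotifHit(mdef.motif_id, "absent")


# ---------------------------------------------------------------------------
# special locators
# ---------------------------------------------------------------------------

_NTA_PAIR = re.compile("(?=[STDE][DE])")


def locate_nta(seq: SequenceRecord, origin: int) -> MotifHit:
    """Acidic/serine NtA pair in the window just N-terminal of the kinase
    domain; the candidate closest to the domain start wins."""
    s = seq.residues
    lo = max(1, origin - 20)
    hi = max(1, origin - 10)
    window = s[lo - 1 : hi + 1]
    matches = list(_NTA_PAIR.finditer(window))
    if not matches:
        return MotifHit("NTA", "absent")
    m = matches[-1]  # rightmost = closest to the domain start
    start = lo + m.start()
    matched = s[start - 1 : start + 1]
    status = "canonical" if matched[0] in "SDE" else "degenerate"
    return MotifHit("NTA", status, start, start + 1, matched, start)


_CTERM_1433 = re.compile("(?=(.S.SEP))")


def locate_cterm_1433(seq: SequenceRecord) -> MotifHit:
    """C-terminal 14-3-3 site X-S-X-S-E-P in the C-terminal third; the key
    residue is the serine preceding E-P."""
    s = seq.residues
    third = max(0, 2 * len(s) // 3)
    m = _CTERM_1433.search(s, third)
    if m is None:
        return MotifHit("CTERM_1433", "absent")
    start = m.start() + 1
    return MotifHit("CTERM_1433", "canonical", start, start + 5,
                    m.group(1), start + 3)


_NTERM_1433 = re.compile("(?=(S..S))")


def locate_nterm_1433(
    seq: SequenceRecord, crd_end: Optional[int], origin: int
) -> MotifHit:
    """Paired serines S-X-X-S in the CRD-to-kinase linker (leftmost)."""
    s = seq.residues
    lo = (crd_end or 0) + 1
    hi = max(lo, origin - 30)
    m = _NTERM_1433.search(s, lo - 1, hi)
    if m is None:
        return MotifHit("NTERM_1433", "absent")
    start = m.start() + 1
    return MotifHit("NTERM_1433", "canonical", start, start + 3, m.group(1), start)


_C1_CRD = re.compile("H.{11,13}C..C.{12,15}C..C")


def locate_c1_crd(seq: SequenceRecord) -> MotifHit:
    """C1 zinc-finger cysteine spacing (relaxed) in the N-terminal half;
    key residue = first cysteine of the match."""
    s = seq.residues
    m = _C1_CRD.search(s, 0, max(len(s) // 2, 80))
    if m is None:
        return MotifHit("C1_CRD", "absent")
    start, end = m.start() + 1, m.end()
    first_c = start + m.group(0).index("C", 1)
    return MotifHit("C1_CRD", "canonical", start, end, m.group(0), first_c)


def detect_domain_by_exemplar(
    seq: SequenceRecord,
    exemplar: SequenceRecord,
    threshold: Optional[float] = None,
) -> Tuple[bool, Optional[Tuple[int, int]], float]:
    """Local-alignment domain detection against an exemplar.

    Present iff the local score reaches ``threshold``; the default
    threshold is half the exemplar's self-alignment score, which sits far
    above the score distribution of shuffled exemplars.  Returns
    ``(present, span_in_seq, score)``.
    """
    params = AlignmentParams(mode="local")
    self_score = pairwise_align(exemplar, exemplar, params).score
    threshold = threshold if threshold is not None else 0.5 * self_score
    aln = pairwise_align(exemplar, seq, params)
    matched = [pb for pa, pb in aln.columns if pa is not None and pb is not None]
    present = aln.score >= threshold and bool(matched)
    span = (matched[0], matched[-1]) if matched else None
    return present, span, aln.score


_ERK_SITE = re.compile("(?=(P.[ST]P))")


def count_erk_feedback_sites(seq: SequenceRecord, domain: Tuple[int, int]) -> int:
    """Number of P-X-[ST]-P matches lying entirely outside the kinase domain."""
    n = 0
    for m in _ERK_SITE.finditer(seq.residues):
        start, end = m.start() + 1, m.start() + 4
        if end < domain[0] or start > domain[1]:
            n += 1
    return n


# ---------------------------------------------------------------------------
# full annotation
# ---------------------------------------------------------------------------

def annotate(
    seq: SequenceRecord,
    catalog: Sequence[MotifDef] = DEFAULT_CATALOG,
    exemplars: Optional[Dict[str, SequenceRecord]] = None,
) -> KinaseAnnotation:
    """Run all locators and assemble the region table and fingerprint.

    Regions are anchored to motif hits: PLOOP = P-loop match; BETA3 = VAIK
    match +-3; ALPHAC = the alphaC window ending 5 past the dimerization
    motif; CATLOOP = the HRD window; AS = DFG through DFG+30; DIF =
    dimerization arginine +-5; BETA7_BETA8 = between catalytic loop and
    DFG.  For degenerate/absent motifs the window centre stands in for the
    missing hit.
    """
    if exemplars is None:
        exemplars = load_exemplars()
    span, low_conf, anchor, origin = locate_kinase_domain(
        seq, exemplars.get("KINASE_DOMAIN_EXEMPLAR")
    )

    hits: Dict[str, MotifHit] = {}
    for mdef in catalog:
        hits[mdef.motif_id] = scan_motif(seq, mdef, span, origin)

    crd = locate_c1_crd(seq)
    hits["C1_CRD"] = crd
    nta = locate_nta(seq, origin)
    hits["NTA"] = nta
    hits["NTERM_1433"] = locate_nterm_1433(seq, crd.end, origin)
    cterm = locate_cterm_1433(seq)
    hits["CTERM_1433"] = cterm

    cc_sam_present, cc_sam_span, _ = detect_domain_by_exemplar(
        seq, exemplars["CC_SAM_EXEMPLAR"]
    )
    rbd_present, rbd_span, _ = detect_domain_by_exemplar(
        seq, exemplars["RBD_EXEMPLAR"]
    )
    erk_count = count_erk_feedback_sites(seq, span)

    def pos_or(mid: str, default: int) -> int:
        h = hits[mid]
        return h.start if h.status != "absent" and h.start else default

    n = len(seq.residues)

    def clamp(a: int, b: int) -> Tuple[int, int]:
        return (max(1, min(a, n)), max(1, min(b, n)))

    ploop_start = pos_or("PLOOP", origin)
    vaik = hits["VAIK"]
    vaik_start = pos_or("VAIK", origin + MOTIF_OFFSETS["VAIK"])
    dimer = hits["DIMER_RKTR"]
    dimer_start = pos_or("DIMER_RKTR", origin + MOTIF_OFFSETS["DIMER_RKTR"])
    dimer_key = dimer.key_position if dimer.status != "absent" else dimer_start + 3
    hrd_start = pos_or("HRD", origin + MOTIF_OFFSETS["HRD"])
    dfg = hits["DFG"]
    dfg_start = pos_or("DFG", origin + MOTIF_OFFSETS["DFG"])

    regions: Dict[str, Tuple[int, int]] = {
        "PLOOP": clamp(ploop_start, ploop_start + 5),
        "BETA3": clamp(vaik_start - 3, vaik_start + 6),
        "ALPHAC": clamp(dimer_start - 12, dimer_start + 8),
        "BETA3_ALPHAC_LOOP": clamp(vaik_start + 7, dimer_start - 13),
        "DIF": clamp(dimer_key - 5, dimer_key + 5),
        "CATLOOP": clamp(hrd_start, hrd_start + 7),
        "BETA7_BETA8": clamp(hrd_start + 8, dfg_start - 1),
        "AS": clamp(dfg_start, dfg_start + AS_LENGTH),
    }
    if nta.status != "absent":
        regions["NTA"] = clamp(nta.start - 4, nta.end)
    if crd.status != "absent":
        regions["CRD"] = (crd.start, crd.end)
    if cc_sam_present and cc_sam_span:
        regions["CC_SAM"] = cc_sam_span

    fingerprint: Dict[str, object] = {
        "has_cc_sam": cc_sam_present,
        "has_rbd": rbd_present,
        "has_crd": crd.status != "absent",
        "ploop_canonical": hits["PLOOP"].status == "canonical",
        "vaik_canonical": vaik.status == "canonical",
        "hrd_present": hits["HRD"].status != "absent",
        "dfg_present": dfg.status != "absent",
        "has_nta_acidic": nta.status != "absent",
        "has_cterm_1433": cterm.status != "absent",
        "erk_feedback_count": erk_count,
    }
    return KinaseAnnotation(
        sequence_id=seq.id,
        kinase_domain=span,
        low_confidence=low_conf,
        anchor=anchor,
        hits=hits,
        regions=regions,
        fingerprint=fingerprint,
    )
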