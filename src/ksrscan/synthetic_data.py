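"""Synthetic RAF / KSR1-2 / KSR3 protein generator with ground truth.

This module builds labelled, fully synthetic protein sequences that realize
the three domain architectures the pipeline analyses:

* ``RAF``    — RBD + CRD + kinase domain with intact catalytic motifs
  (G-X-G-X-X-G P-loop, VAIK lysine, HRD, DFG), an N-terminal acidic (NtA)
  SSDD motif, the basic RKTR dimerization motif, and ERK feedback sites.
* ``KSR1_2`` — CC-SAM + proline-rich + CRD + kinase domain with an HKD-type
  catalytic loop (otherwise intact motifs), dimerization arginine intact.
* ``KSR3``   — CRD + kinase domain with a degenerate P-loop (EXGXXG) and
  VLIQ in place of VAIK, *no* HRD, *no* DFG, a beta3-alphaC region three
  residues shorter than RAF/KSR1 (the VTA deletion), a neutral SKIR/SRIR/
  SMIR dimerization motif, an NtA acidic pair, and a C-terminal X-S-X-S-E-P
  14-3-3 motif.

Every sequence is assembled from a master table of aligned blocks, so the
generator knows the true multiple alignment of everything it emits, and
every landmark position is recorded in a :class:`GroundTruth` that is
validated against the emitted residues at construction time.

The five base templates are SYNTHETIC stand-ins, not natural sequences:
they reproduce the residue-numbering layout reported in the literature for
human B-RAF (e.g. P-loop G464/G466/G469, VAIK K483, catalytic D576, DFG
D594, RKTR 506-509, activation-segment V600), for the sea urchin
(*Paracentrotus lividus*) KSR3 (CRD C37/C40, 14-3-3 serines S84/S87 and
S586, NtA S306/E307, beta3 R343, alphaC L354, SKIR 361-364, beta7-beta8
K443/V444, activation-segment D452/D455), for sea urchin KSR1 (R608), for
the hemichordate (*Saccoglossus*) KSR3 (NtA D293/E294, R350, S572) and for
the cnidarian (*Nematostella*) KSR3 (R390, S618) — so that coordinate
liftover and motif scans can be exercised against published numbering
without any natural sequence data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "ArchetypeSpec",
    "GroundTruth",
    "FAMILIES",
    "BASES",
    "make_archetype",
    "make_family_set",
    "make_ksr3_divergence_set",
    "inject_mutation",
    "reference_records",
    "reference_truths",
    "reference_msa_rows",
    "cc_sam_exemplar",
    "rbd_exemplar",
    "kinase_domain_exemplar",
]

Family = Literal["RAF", "KSR1_2", "KSR3"]
FAMILIES: Tuple[Family, ...] = ("RAF", "KSR1_2", "KSR3")

# base templates (columns of the master alignment); KSR3 comes in three
# species flavours that differ in linker lengths and motif variants.
BASES = ("BRAF", "KSR1", "KSR3_PL", "KSR3_SK", "KSR3_NV")
BASE_FAMILY: Dict[str, Family] = {
    "BRAF": "RAF",
    "KSR1": "KSR1_2",
    "KSR3_PL": "KSR3",
    "KSR3_SK": "KSR3",
    "KSR3_NV": "KSR3",
}

# Fillers deliberately avoid G, C, P, S, D, E, H, R so that no spurious
# P-loop, CRD cysteine pattern, ERK feedback site, acidic NtA pair,
# 14-3-3 serine pair or HRD/DFG match can arise in linker sequence.
FILLER_ALPHABET = "AVLIMQNKYTWF"
PROTEIN20 = "ACDEFGHIKLMNPQRSTVWY"


def _filler(n: int, key: str) -> str:
    """Deterministic pseudo-random filler; lowercase marks it mutable."""
    rng = np.random.default_rng(zlib.crc32(key.encode()) & 0x7FFFFFFF)
    return "".join(rng.choice(list(FILLER_ALPHABET), size=n)).lower()


# ---------------------------------------------------------------------------
# master block table
# ---------------------------------------------------------------------------
# Each block maps base -> content string; uppercase residues are protected
# (motif cores and landmark residues, excluded from substitution noise),
# lowercase are mutable filler.  Absent content ("") renders as gap columns
# in the master alignment.  Within a block, shorter contents are right-
# padded with gaps.

_CRD_CORE = "H" + _filler(12, "crd_f1") + "C" + _filler(2, "crd_f2") + "C" \
    + _filler(12, "crd_f3") + "C" + _filler(2, "crd_f4") + "C"


def _blocks() -> List[Tuple[str, Dict[str, str]]]:
    f = _filler
    ccsam = f(80, "ccsam_exemplar")
    rbd = f(73, "rbd_exemplar")
    linker_b_common = f(203, "linker_b")
    blocks: List[Tuple[str, Dict[str, str]]] = [
        ("nterm", {
            "BRAF": "M" + f(29, "braf_nt1") + "PQSP" + f(120, "braf_nt2"),
            "KSR1": "M" + f(24, "ksr1_nt"),
            "KSR3_PL": "MQPKEHI" + f(16, "pl_nt"),
            "KSR3_SK": "M" + f(22, "sk_nt"),
            "KSR3_NV": "M" + f(22, "nv_nt"),
        }),
        ("cc_sam", {"KSR1": ccsam}),
        ("pro_rich", {
            "KSR1": f(30, "pr1") + "PVSP" + f(20, "pr2") + "PGTP" + f(34, "pr3"),
        }),
        ("rbd", {"BRAF": rbd}),
        ("linker_a", {"BRAF": f(6, "la"), "KSR1": f(6, "la")}),
        ("crd_core", {b: _CRD_CORE for b in BASES}),
        ("crd_tail", {
            "BRAF": f(14, "crdt"), "KSR1": f(14, "crdt"),
            "KSR3_PL": f(14, "crdt") + f(5, "crdt_k3"),
            "KSR3_SK": f(14, "crdt") + f(5, "crdt_k3"),
            "KSR3_NV": f(14, "crdt") + f(5, "crdt_k3"),
        }),
        ("linker_b", {
            "BRAF": f(84, "braf_lb1") + "SVAS" + f(77, "braf_lb2"),
            "KSR1": f(60, "ksr1_lb1") + "SVAS" + f(230, "ksr1_lb2"),
            "KSR3_PL": f(8, "k3_lb0") + "SAAS" + linker_b_common + f(13, "pl_lb3"),
            "KSR3_SK": f(8, "k3_lb0") + "SAAS" + linker_b_common,
            "KSR3_NV": f(8, "k3_lb0") + "SAAS" + linker_b_common + f(13, "nv_lb3"),
        }),
        ("linker_nv_extra", {"KSR3_NV": f(26, "nv_extra")}),
        ("nta", {
            "BRAF": "SSDD", "KSR1": "SSDD",
            "KSR3_PL": "SSSE", "KSR3_SK": "SSDE", "KSR3_NV": "SSSE",
        }),
        ("pre_ploop", {
            "BRAF": f(14, "prep"), "KSR1": f(14, "prep"),
            "KSR3_PL": f(14, "prep"), "KSR3_SK": f(13, "prep_sk"),
            "KSR3_NV": f(14, "prep"),
        }),
        ("ploop", {
            "BRAF": "GSGSFG", "KSR1": "GSGSFG",
            "KSR3_PL": "ESGSNG", "KSR3_SK": "ESGSNG", "KSR3_NV": "ESGSNG",
        }),
        ("b2b3", {b: f(10, "b2b3") for b in BASES}),
        ("vaik", {
            "BRAF": "VAVK", "KSR1": "VAVK",
            "KSR3_PL": "VLIQ", "KSR3_SK": "VLIQ", "KSR3_NV": "VLIQ",
        }),
        ("beta3", {
            "BRAF": "MLN", "KSR1": "MLN",
            "KSR3_PL": "MRN", "KSR3_SK": "MRN", "KSR3_NV": "MRN",
        }),
        ("vta", {"BRAF": "VTA", "KSR1": "VTA"}),  # deleted in KSR3
        ("b3ac_loop", {b: "PTP" for b in BASES}),
        ("qlqa", {
            "BRAF": "QLQA", "KSR1": "QLQA",
            "KSR3_PL": "DIND", "KSR3_SK": "DIND", "KSR3_NV": "DIND",
        }),
        ("post_qlqa", {b: "FN" for b in BASES}),
        ("k499", {
            "BRAF": "K", "KSR1": "K",
            "KSR3_PL": "L", "KSR3_SK": "L", "KSR3_NV": "L",
        }),
        ("alphac", {b: "EVGVAL" for b in BASES}),
        ("dif", {
            "BRAF": "RKTR", "KSR1": "RKTR",
            "KSR3_PL": "SKIR", "KSR3_SK": "SRIR", "KSR3_NV": "SMIR",
        }),
        ("alphac_b4", {b: f(10, "acb4") for b in BASES}),
        ("ksr3_insert", {"KSR3_PL": "Q", "KSR3_SK": "Q", "KSR3_NV": "Q"}),
        ("midlobe", {b: f(54, "midlobe") for b in BASES}),
        ("catloop", {
            "BRAF": "HRD", "KSR1": "HKD",
            "KSR3_PL": "TLN", "KSR3_SK": "TLN", "KSR3_NV": "TLN",
        }),
        ("catloop_tail", {b: "LKSNN" for b in BASES}),
        ("b7b8", {
            "BRAF": "IFLHEDLTVKIG", "KSR1": "IFLHEDLTVKIG",
            "KSR3_PL": "IFLHEKVTVKIG", "KSR3_SK": "IFLHEKVTVKIG",
            "KSR3_NV": "IFLHEKVTVKIG",
        }),
        ("dfg", {
            "BRAF": "DFG", "KSR1": "DFG",
            "KSR3_PL": "SVD", "KSR3_SK": "SVD", "KSR3_NV": "SVD",
        }),
        ("as_tail", {
            "BRAF": "LATVKSR" + f(18, "as_raf") + "APE",
            "KSR1": "LATVKSR" + f(18, "as_raf") + "APE",
            "KSR3_PL": "TSDVKSR" + f(18, "as_k3") + "APE",
            "KSR3_SK": "TSDVKSR" + f(18, "as_k3") + "APE",
            "KSR3_NV": "TSDVKSR" + f(18, "as_k3") + "APE",
        }),
        ("clobe", {b: f(93, "clobe") for b in BASES}),
        ("postlobe", {
            "BRAF": f(7, "postl"), "KSR1": f(7, "postl"),
            "KSR3_PL": f(9, "postl_k3"), "KSR3_SK": f(9, "postl_k3"),
            "KSR3_NV": f(9, "postl_k3"),
        }),
        ("ctail_nv_extra", {"KSR3_NV": f(6, "nv_ct")}),
        ("cterm_1433", {
            "BRAF": "RSHSEP", "KSR1": "RSHSEP",
            "KSR3_PL": "HSLSEP", "KSR3_SK": "HSQSEP", "KSR3_NV": "GSHSEP",
        }),
        ("tail", {
            "BRAF": f(7, "braf_t1") + "PQSP" + f(25, "braf_t2"),
            "KSR1": f(20, "ksr1_t"),
            "KSR3_PL": f(10, "k3_t"), "KSR3_SK": f(10, "k3_t"),
            "KSR3_NV": f(10, "k3_t"),
        }),
    ]
    return blocks


_BLOCK_TABLE = _blocks()
_BLOCK_INDEX = {name: i for i, (name, _) in enumerate(_BLOCK_TABLE)}
# blocks where noise-model indels are allowed (pure linker sequence)
_INDEL_BLOCKS = {"nterm", "linker_b", "tail"}


def _content(base: str, block: str) -> str:
    return _BLOCK_TABLE[_BLOCK_INDEX[block]][1].get(base, "")


def _block_start(base: str, block: str) -> int:
    """1-based sequence position of the first residue of ``block``."""
    pos = 0
    for name, contents in _BLOCK_TABLE:
        if name == block:
            return pos + 1
        pos += len(contents.get(base, ""))
    raise KeyError(block)


def _sequence(base: str) -> str:
    return "".join(c.get(base, "") for _, c in _BLOCK_TABLE).upper()


def _msa_row(base: str) -> str:
    parts = []
    for _, contents in _BLOCK_TABLE:
        width = max(len(v) for v in contents.values())
        content = contents.get(base, "")
        parts.append(content.upper() + "-" * (width - len(content)))
    return "".join(parts)


# ---------------------------------------------------------------------------
# landmarks (positions derived from the block table, residues asserted)
# ---------------------------------------------------------------------------

def _landmark_defs(base: str) -> Dict[str, Tuple[str, int, str]]:
    """name -> (block, 0-based offset in block content, expected residue)."""
    if base == "BRAF":
        return {
            "G464": ("ploop", 0, "G"), "G466": ("ploop", 2, "G"),
            "F468": ("ploop", 4, "F"), "G469": ("ploop", 5, "G"),
            "K483": ("vaik", 3, "K"), "L485": ("beta3", 1, "L"),
            "V487": ("vta", 0, "V"),
            "Q493": ("qlqa", 0, "Q"), "A496": ("qlqa", 3, "A"),
            "F497": ("post_qlqa", 0, "F"), "K499": ("k499", 0, "K"),
            "L505": ("alphac", 5, "L"),
            "R506": ("dif", 0, "R"), "T508": ("dif", 2, "T"),
            "R509": ("dif", 3, "R"),
            "D576": ("catloop", 2, "D"),
            "D587": ("b7b8", 5, "D"), "L588": ("b7b8", 6, "L"),
            "D594": ("dfg", 0, "D"), "L597": ("as_tail", 0, "L"),
            "T599": ("as_tail", 2, "T"), "V600": ("as_tail", 3, "V"),
            "S446": ("nta", 0, "S"), "D449": ("nta", 3, "D"),
        }
    if base == "KSR1":
        return {"R608": ("dif", 3, "R")}
    common = {
        "C37": ("crd_core", 13, "C"), "C40": ("crd_core", 16, "C"),
        "S84": ("linker_b", 8, "S"), "S87": ("linker_b", 11, "S"),
    }
    if base == "KSR3_PL":
        return {**common,
                "S306": ("nta", 2, "S"), "E307": ("nta", 3, "E"),
                "R343": ("beta3", 1, "R"), "L354": ("k499", 0, "L"),
                "S361": ("dif", 0, "S"), "K362": ("dif", 1, "K"),
                "I363": ("dif", 2, "I"), "R364": ("dif", 3, "R"),
                "K443": ("b7b8", 5, "K"), "V444": ("b7b8", 6, "V"),
                "D452": ("dfg", 2, "D"), "D455": ("as_tail", 2, "D"),
                "S586": ("cterm_1433", 3, "S")}
    if base == "KSR3_SK":
        return {**common,
                "D293": ("nta", 2, "D"), "E294": ("nta", 3, "E"),
                "R350": ("dif", 3, "R"), "S572": ("cterm_1433", 3, "S")}
    if base == "KSR3_NV":
        return {"R390": ("dif", 3, "R"), "S618": ("cterm_1433", 3, "S")}
    raise KeyError(base)


# motif ground-truth status per base template
_MOTIF_TRUTH: Dict[str, Dict[str, str]] = {
    "BRAF": {"PLOOP": "canonical", "VAIK": "canonical", "HRD": "canonical",
             "DFG": "canonical", "DIMER_RKTR": "canonical"},
    "KSR1": {"PLOOP": "canonical", "VAIK": "canonical", "HRD": "degenerate",
             "DFG": "canonical", "DIMER_RKTR": "canonical"},
    "KSR3_PL": {"PLOOP": "degenerate", "VAIK": "degenerate", "HRD": "absent",
                "DFG": "absent", "DIMER_RKTR": "degenerate"},
}
_MOTIF_TRUTH["KSR3_SK"] = _MOTIF_TRUTH["KSR3_PL"]
_MOTIF_TRUTH["KSR3_NV"] = _MOTIF_TRUTH["KSR3_PL"]

_FINGERPRINT_TRUTH: Dict[str, Dict[str, bool]] = {
    "BRAF": dict(has_cc_sam=False, has_rbd=True, has_crd=True,
                 ploop_canonical=True, vaik_canonical=True, hrd_present=True,
                 dfg_present=True, has_nta_acidic=True, has_cterm_1433=True),
    "KSR1": dict(has_cc_sam=True, has_rbd=False, has_crd=True,
                 ploop_canonical=True, vaik_canonical=True, hrd_present=True,
                 dfg_present=True, has_nta_acidic=True, has_cterm_1433=True),
    "KSR3_PL": dict(has_cc_sam=False, has_rbd=False, has_crd=True,
                    ploop_canonical=False, vaik_canonical=False,
                    hrd_present=False, dfg_present=False,
                    has_nta_acidic=True, has_cterm_1433=True),
}
_FINGERPRINT_TRUTH["KSR3_SK"] = _FINGERPRINT_TRUTH["KSR3_PL"]
_FINGERPRINT_TRUTH["KSR3_NV"] = _FINGERPRINT_TRUTH["KSR3_PL"]

_ERK_SITE_TRUTH = {"BRAF": 2, "KSR1": 2, "KSR3_PL": 0, "KSR3_SK": 0, "KSR3_NV": 0}


@dataclass
class GroundTruth:
    """What the generator actually embedded in one emitted sequence."""

    family: Family
    base: str
    landmarks: Dict[str, int]
    motif_status: Dict[str, str]
    fingerprint: Dict[str, bool]
    erk_feedback_count: int
    kinase_domain: Tuple[int, int]
    ploop_start: int
    dimer_key: int
    protected: frozenset = field(default_factory=frozenset)
    injected: List[str] = field(default_factory=list)
    aligned_row: Optional[str] = None  # master-alignment row (None with indels)

    def validate(self, residues: str) -> None:
        for name, pos in self.landmarks.items():
            expected = name[0]
            actual = residues[pos - 1]
            if actual != expected:
                raise AssertionError(
                    f"{self.base}: landmark {name} at {pos} reads {actual!r}"
                )


@dataclass(frozen=True)
class ArchetypeSpec:
    """Recipe for one synthetic sequence.

    noise is the per-site substitution probability applied to mutable
    (non-motif) positions; indel_rate applies 1-residue indels within
    linker blocks only, so landmark identities survive (their positions
    shift and are re-reported in the truth).
    """

    family: Family
    base: Optional[str] = None
    noise: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0
    scramble_motifs: bool = False
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        base = self.base or {"RAF": "BRAF", "KSR1_2": "KSR1", "KSR3": "KSR3_PL"}[self.family]
        if BASE_FAMILY[base] != self.family:
            raise ValueError(f"base {base!r} is not a {self.family} template")
        object.__setattr__(self, "base", base)
        if not 0.0 <= self.noise <= 0.5:
            raise ValueError("noise must be in [0, 0.5]")
        if not 0.0 <= self.indel_rate <= 0.2:
            raise ValueError("indel_rate must be in [0, 0.2]")


def _tokens(base: str):
    """Per-residue tokens: (char, protected?, block name, offset in block)."""
    toks = []
    for name, contents in _BLOCK_TABLE:
        content = contents.get(base, "")
        for off, ch in enumerate(content):
            toks.append([ch.upper(), ch.isupper(), name, off])
    return toks


def make_archetype(spec: ArchetypeSpec) -> Tuple[SequenceRecord, GroundTruth]:
    """Emit one synthetic sequence plus its self-validated ground truth.

    Deterministic for a fixed spec (one RNG stream seeded from
    ``spec.seed``).  At zero noise and zero indel rate the sequence equals
    the base template exactly.
    """
    rng = np.random.default_rng(spec.seed)
    toks = _tokens(spec.base)

    if spec.indel_rate > 0:
        kept = []
        for tok in toks:
            if tok[2] in _INDEL_BLOCKS and not tok[1]:
                r = rng.random()
                if r < spec.indel_rate / 2:
                    continue  # deletion
                kept.append(tok)
                if r > 1 - spec.indel_rate / 2:  # insertion after this site
                    kept.append([rng.choice(list(FILLER_ALPHABET)), False, tok[2], -1])
            else:
                kept.append(tok)
        toks = kept

    if spec.noise > 0:
        for tok in toks:
            if (spec.scramble_motifs or not tok[1]) and rng.random() < spec.noise:
                alternatives = [a for a in PROTEIN20 if a != tok[0]]
                tok[0] = alternatives[rng.integers(len(alternatives))]

    residues = "".join(t[0] for t in toks)
    posmap: Dict[Tuple[str, int], int] = {}
    for i, (_, _, blk, off) in enumerate(toks, start=1):
        if off >= 0:
            posmap[(blk, off)] = i

    landmarks = {}
    for name, (blk, off, expected) in _landmark_defs(spec.base).items():
        pos = posmap[(blk, off)]
        landmarks[name] = pos

    ploop_start = posmap[("ploop", 0)]
    dimer_key = posmap[("dif", 3)]
    as_end = posmap[("as_tail", 27)]
    domain = (ploop_start, min(len(residues), as_end + 30))
    protected = frozenset(i for i, t in enumerate(toks, start=1) if t[1])

    aligned_row = None
    if spec.indel_rate == 0:
        # without indels the tokens map 1:1 onto the base template, so the
        # master-alignment row is the padded block layout with noise applied
        parts: List[str] = []
        tok_i = 0
        for name, contents in _BLOCK_TABLE:
            width = max(len(v) for v in contents.values())
            n_here = len(contents.get(spec.base, ""))
            chars = "".join(toks[tok_i + k][0] for k in range(n_here))
            tok_i += n_here
            parts.append(chars + "-" * (width - n_here))
        aligned_row = "".join(parts)

    truth = GroundTruth(
        family=spec.family,
        base=spec.base,
        landmarks=landmarks,
        motif_status=dict(_MOTIF_TRUTH[spec.base]),
        fingerprint=dict(_FINGERPRINT_TRUTH[spec.base]),
        erk_feedback_count=_ERK_SITE_TRUTH[spec.base],
        kinase_domain=domain,
        ploop_start=ploop_start,
        dimer_key=dimer_key,
        protected=protected,
        aligned_row=aligned_row,
    )
    if not spec.scramble_motifs:
        truth.validate(residues)

    label = spec.label or f"{spec.base}_s{spec.seed}"
    rec = SequenceRecord(label, residues, "protein",
                         description=f"synthetic {spec.family} archetype")
    return rec, truth


def make_family_set(
    n_per_family: int,
    noise: float = 0.02,
    seed: int = 0,
    indel_rate: float = 0.0,
) -> Tuple[List[SequenceRecord], List[GroundTruth]]:
    """3n labelled sequences (n per family) with a shared noise level.

    KSR3 members rotate through the three species flavours.  Sequences are
    tagged with a pseudo-species label (``spNN``) such that species ``i``
    carries exactly one RAF, one KSR1_2 and one KSR3 gene, mirroring a
    one-each gene complement.
    """
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    ksr3_bases = ("KSR3_PL", "KSR3_SK", "KSR3_NV")
    records, truths = [], []
    for i in range(n_per_family):
        for family in FAMILIES:
            base = ksr3_bases[i % 3] if family == "KSR3" else None
            sub_seed = (seed * 7919 + i * 13 + FAMILIES.index(family)) % (2**31)
            spec = ArchetypeSpec(family, base=base, noise=noise,
                                 indel_rate=indel_rate, seed=sub_seed,
                                 label=f"{family}_sp{i:02d}")
            rec, truth = make_archetype(spec)
            rec = replace(rec, description=rec.description + f" species=sp{i:02d}")
            records.append(rec)
            truths.append(truth)
    return records, truths


# ---------------------------------------------------------------------------
# divergence-profile study set
# ---------------------------------------------------------------------------

def _braf_region_cols() -> Dict[str, Tuple[int, int]]:
    """Master-alignment column spans of the divergence hotspot regions,
    expressed through B-RAF content positions."""
    row = _msa_row("BRAF")
    # map B-RAF sequence position -> master column
    col_of = {}
    p = 0
    for c, ch in enumerate(row, start=1):
        if ch != "-":
            p += 1
            col_of[p] = c
    ploop = (_block_start("BRAF", "ploop"), _block_start("BRAF", "ploop") + 5)
    dif_end = _block_start("BRAF", "dif") + 3
    alphac = (dif_end - 15, dif_end + 5)
    dfg = _block_start("BRAF", "dfg")
    as_ = (dfg, dfg + 30)
    return {name: (col_of[a], col_of[b])
            for name, (a, b) in {"PLOOP": ploop, "ALPHAC": alphac, "AS": as_}.items()}


def make_ksr3_divergence_set(
    n: int,
    seed: int = 0,
    hotspot_rate: float = 0.35,
    base_noise: float = 0.02,
) -> Tuple[List[str], List[str]]:
    """Aligned rows for a divergence-profile study: a RAF reference plus
    ``n`` KSR3 variants whose extra substitutions are concentrated in the
    P-loop, alphaC and activation-segment columns.

    Returns ``(ids, gapped_rows)`` with the reference first; rows are
    restricted to the kinase-domain columns (NtA through the C-terminal
    14-3-3 motif), which is where a divergence profile against a kinase is
    meaningful.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    hot = _braf_region_cols()
    hot_cols = set()
    for a, b in hot.values():
        hot_cols.update(range(a, b + 1))

    ref_row = _msa_row("BRAF")
    rows = [ref_row]
    ids = ["BRAF_REF"]
    bases = ("KSR3_PL", "KSR3_SK", "KSR3_NV")
    for i in range(n):
        row = list(_msa_row(bases[i % 3]))
        for c, ch in enumerate(row, start=1):
            if ch == "-":
                continue
            rate = hotspot_rate if c in hot_cols else base_noise
            if rng.random() < rate:
                alternatives = [a for a in PROTEIN20 if a != ch]
                row[c - 1] = alternatives[rng.integers(len(alternatives))]
        rows.append("".join(row))
        ids.append(f"KSR3_div{i:02d}")

    # restrict to the kinase region: NtA block through the 14-3-3 motif
    start_col = sum(max(len(v) for v in c.values())
                    for name, c in _BLOCK_TABLE[: _BLOCK_INDEX["nta"]])
    end_col = sum(max(len(v) for v in c.values())
                  for name, c in _BLOCK_TABLE[: _BLOCK_INDEX["cterm_1433"] + 1])
    rows = [r[start_col:end_col] for r in rows]
    return ids, rows


# ---------------------------------------------------------------------------
# mutation injection
# ---------------------------------------------------------------------------

def inject_mutation(record: SequenceRecord, m) -> SequenceRecord:
    """Apply a candidate mutation (substitution / deletion / segment swap).

    The acceptor residue(s) must match the record at the stated position —
    a guard against numbering drift.  The returned record's id carries the
    mutation label.
    """
    seq = record.residues
    pos = m.acceptor_position
    if m.kind == "substitution":
        if seq[pos - 1] != m.acceptor_residue:
            raise ValueError(
                f"wild-type mismatch at {pos}: sequence has {seq[pos-1]!r}, "
                f"expected {m.acceptor_residue!r}"
            )
        new = seq[: pos - 1] + m.payload + seq[pos:]
    elif m.kind == "deletion":
        span = len(m.acceptor_residue)
        if seq[pos - 1 : pos - 1 + span] != m.acceptor_residue:
            raise ValueError(f"wild-type mismatch for deletion at {pos}")
        new = seq[: pos - 1] + seq[pos - 1 + span :]
    elif m.kind == "segment_swap":
        span = len(m.acceptor_residue)
        if seq[pos - 1 : pos - 1 + span] != m.acceptor_residue:
            raise ValueError(f"wild-type mismatch for segment swap at {pos}")
        new = seq[: pos - 1] + m.payload + seq[pos - 1 + span :]
    else:
        raise ValueError(f"unknown mutation kind {m.kind!r}")
    return SequenceRecord(
        f"{record.id}_{m.label}", new, record.alphabet,
        description=(record.description + f" {m.label}").strip(),
    )


# ---------------------------------------------------------------------------
# packaged synthetic references and exemplars
# ---------------------------------------------------------------------------

def reference_records() -> Dict[str, SequenceRecord]:
    """The five zero-noise synthetic base templates, keyed by template name."""
    out = {}
    for base in BASES:
        rec, _ = make_archetype(ArchetypeSpec(BASE_FAMILY[base], base=base, label=base))
        out[base] = rec
    return out


def reference_truths() -> Dict[str, GroundTruth]:
    out = {}
    for base in BASES:
        _, truth = make_archetype(ArchetypeSpec(BASE_FAMILY[base], base=base, label=base))
        out[base] = truth
    return out


def reference_msa_rows() -> Dict[str, str]:
    """Ground-truth master alignment rows for the five base templates."""
    return {base: _msa_row(base) for base in BASES}


def cc_sam_exemplar() -> SequenceRecord:
    """Synthetic CC-SAM domain exemplar (the KSR1 template's CC-SAM block)."""
    return SequenceRecord("CC_SAM_EXEMPLAR", _content("KSR1", "cc_sam").upper(),
                          "protein", "synthetic CC-SAM domain exemplar")


def rbd_exemplar() -> SequenceRecord:
    """Synthetic RAS-binding-domain exemplar (the RAF template's RBD block)."""
    return SequenceRecord("RBD_EXEMPLAR", _content("BRAF", "rbd").upper(),
                          "protein", "synthetic RAS-binding domain exemplar")


def kinase_domain_exemplar() -> SequenceRecord:
    """Synthetic canonical kinase-domain exemplar (RAF template, P-loop
    block through the activation-segment end), used to anchor kinase-domain
    location in sequences whose own motifs are too degenerate to anchor."""
    seq = _sequence("BRAF")
    start = _block_start("BRAF", "ploop")
    end = _block_start("BRAF", "clobe") - 1
    return SequenceRecord("KINASE_DOMAIN_EXEMPLAR", seq[start - 1 : end],
                          "protein", "synthetic canonical kinase domain exemplar")


# offsets of the canonical motif sites inside the kinase exemplar, used by
# the motif scanner to centre its search windows after exemplar anchoring
def exemplar_motif_offsets() -> Dict[str, int]:
    """0-based offsets of motif starts within the kinase-domain exemplar."""
    origin = _block_start("BRAF", "ploop")
    return {
        "PLOOP": _block_start("BRAF", "ploop") - origin,
        "VAIK": _block_start("BRAF", "vaik") - origin,
        "DIMER_RKTR": _block_start("BRAF", "dif") - origin,
        "HRD": _block_start("BRAF", "catloop") - origin,
        "DFG": _block_start("BRAF", "dfg") - origin,
        "NTA": _block_start("BRAF", "nta") - origin,  # negative (upstream)
        "AS_END": _block_start("BRAF", "clobe") - 1 - origin,
    }
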