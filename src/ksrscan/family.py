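"""RAF / KSR1-2 / KSR3 classification and distance-tree corroboration.

Classification reads the architecture fingerprint produced by
:mod:`ksrscan.motifs` with the rule precedence the three families'
discriminating domains impose: an RBD makes a RAF; otherwise a CC-SAM
domain makes a KSR1/2; otherwise a CRD combined with missing HRD *and*
DFG catalytic motifs makes a KSR3; anything else is UNKNOWN (preferred
over guessing when fingerprints conflict, e.g. RBD and CC-SAM both
present).

Groupings are corroborated by a neighbor-joining tree with nonparametric
bootstrap over alignment columns and majority-rule support values mapped
onto the full-data tree.  NJ here is a packaged distance-based
approximation; likelihood tree inference is out of scope.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import skbio
from skbio.tree import TreeNode

from .motifs import KinaseAnnotation

__all__ = [
    "FamilyCall",
    "DistanceMatrix",
    "PhyloTree",
    "classify",
    "distance_matrix",
    "nj_tree",
    "bootstrap_tree",
    "complement_table",
]

Label = Literal["RAF", "KSR1_2", "KSR3", "UNKNOWN"]


@dataclass(frozen=True)
class FamilyCall:
    sequence_id: str
    label: Label
    rule_trace: Tuple[str, ...]
    confidence: Literal["high", "low"]


def classify(annotation: KinaseAnnotation) -> FamilyCall:
    """Pure function of the fingerprint; identical fingerprints always
    yield identical labels."""
    fp = annotation.fingerprint
    trace: List[str] = []
    conflict = fp["has_rbd"] and fp["has_cc_sam"]
    if conflict:
        trace.append("conflict: RBD and CC-SAM both present")
        label: Label = "UNKNOWN"
    elif fp["has_rbd"]:
        trace.append("has_rbd -> RAF")
        label = "RAF"
    elif fp["has_cc_sam"]:
        trace.append("no RBD; has_cc_sam -> KSR1_2")
        label = "KSR1_2"
    elif fp["has_crd"] and not fp["dfg_present"] and not fp["hrd_present"]:
        trace.append("no RBD/CC-SAM; has_crd and HRD+DFG missing -> KSR3")
        label = "KSR3"
    else:
        trace.append("no rule set fully satisfied")
        label = "UNKNOWN"
    confidence = "low" if (annotation.low_confidence or label == "UNKNOWN") else "high"
    return FamilyCall(annotation.sequence_id, label, tuple(trace), confidence)


# ---------------------------------------------------------------------------
# distances and trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    ids: Tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0) or (v < 0).any():
            raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")
        object.__setattr__(self, "values", v)


@dataclass
class PhyloTree:
    """Unrooted tree over taxon ids with optional bootstrap supports."""

    tree: TreeNode

    @property
    def taxa(self) -> frozenset:
        return frozenset(t.name for t in self.tree.tips())

    def newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return cls(TreeNode.read(io.StringIO(text)))

    def bipartitions(self) -> set:
        """Canonical non-trivial splits as frozensets of the smaller side."""
        return _bipartitions(self.tree)


def _bipartitions(tree: TreeNode) -> set:
    all_taxa = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_taxa) - 1:
            other = all_taxa - side
            splits.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return splits


def distance_matrix(msa, correction: Literal["p", "poisson"] = "p") -> DistanceMatrix:
    """Pairwise p-distances from an MSA (fraction of differing residue
    columns, pairwise deletion), optionally Poisson-corrected -ln(1-p).

    ``msa`` is any object with ``ids`` and equal-length ``rows`` gapped
    strings (see :class:`ksrscan.compare.MultipleAlignment`).
    """
    ids = tuple(msa.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    arr = np.array([list(r) for r in msa.rows])
    gap = arr == "-"
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            if not shared.any():
                raise ValueError(f"no shared residue columns between {ids[i]} and {ids[j]}")
            p = float((arr[i][shared] != arr[j][shared]).mean())
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError(f"Poisson correction undefined at p=1 ({ids[i]},{ids[j]})")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids, d)


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining (negative branch lengths clamped to 0)."""
    if len(d.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = skbio.DistanceMatrix(d.values, ids=list(d.ids))
    tree = skbio.tree.nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return PhyloTree(tree)


def bootstrap_tree(
    msa,
    replicates: int = 1000,
    seed: int = 0,
    correction: Literal["p", "poisson"] = "p",
) -> Tuple[PhyloTree, Dict[frozenset, float]]:
    """NJ tree with nonparametric bootstrap supports.

    Alignment columns are resampled with replacement ``replicates`` times,
    a NJ tree is rebuilt per replicate, and each internal node of the
    full-data tree is annotated with the percentage of replicates whose
    tree contains the same bipartition (majority-rule mapping).  Returns
    the annotated tree and the split -> support map.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if len(list(msa.ids)) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    rng = np.random.default_rng(seed)
    full = nj_tree(distance_matrix(msa, correction))
    counts: Dict[frozenset, int] = {split: 0 for split in full.bipartitions()}

    arr = np.array([list(r) for r in msa.rows])
    ncols = arr.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        res = _ArrayMSA(tuple(msa.ids), ["".join(row) for row in arr[:, cols]])
        rep_tree = nj_tree(distance_matrix(res, correction))
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1

    supports = {s: 100.0 * c / replicates for s, c in counts.items()}
    all_taxa = full.taxa
    for node in full.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, all_taxa - side, key=lambda s: (len(s), tuple(sorted(s))))
        if key in supports:
            node.name = f"{supports[key]:.0f}"
    return full, supports


@dataclass(frozen=True)
class _ArrayMSA:
    ids: Tuple[str, ...]
    rows: List[str]


def complement_table(
    calls: Sequence[FamilyCall], species_of: Dict[str, str]
) -> pd.DataFrame:
    """Per-species gene-complement counts of RAF / KSR1_2 / KSR3 calls.

    One row per species, columns RAF, KSR1_2, KSR3, UNKNOWN.
    """
    cols = ["RAF", "KSR1_2", "KSR3", "UNKNOWN"]
    rows: Dict[str, Dict[str, int]] = {}
    for call in calls:
        sp = species_of.get(call.sequence_id, "unassigned")
        rows.setdefault(sp, {c: 0 for c in cols})[call.label] += 1
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols).fillna(0).astype(int)
    df.index.name = "species"
    return df.sort_index()
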