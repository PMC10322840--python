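"""Independent brute-force oracles used by the test suite.

These deliberately avoid dynamic programming and tree reconstruction so
they stay independent of the implementation paths they check.
"""

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _gap_cost(length: int, gap_open: float, gap_extend: float) -> float:
    return gap_open + (length - 1) * gap_extend if length > 0 else 0.0


def enumerate_global_score(a: str, b: str, gap_open: float = 11.0,
                           gap_extend: float = 1.0) -> float:
    """Optimal global affine-gap score by exhaustive enumeration.

    Every global alignment corresponds to a monotone matching of residue
    indices; between consecutive matched columns the cheapest arrangement
    of the unmatched residues is one contiguous gap run per sequence.  The
    optimum is therefore the maximum over all monotone matchings of the
    substitution total minus the run gap costs.
    """
    m, n = len(a), len(b)
    best = -float("inf")
    for k in range(min(m, n) + 1):
        for idx_a in combinations(range(m), k):
            for idx_b in combinations(range(n), k):
                subs = sum(_BLOSUM62[a[i], b[j]] for i, j in zip(idx_a, idx_b))
                cost = 0.0
                prev_i, prev_j = -1, -1
                for i, j in zip(idx_a, idx_b):
                    cost += _gap_cost(i - prev_i - 1, gap_open, gap_extend)
                    cost += _gap_cost(j - prev_j - 1, gap_open, gap_extend)
                    prev_i, prev_j = i, j
                cost += _gap_cost(m - prev_i - 1, gap_open, gap_extend)
                cost += _gap_cost(n - prev_j - 1, gap_open, gap_extend)
                best = max(best, subs - cost)
    return best


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random unrooted binary tree with positive branch lengths and its
    additive distance matrix (path lengths), built without any tree
    library: taxa are joined agglomeratively at random.

    Returns (taxa, distance matrix, set of nontrivial bipartitions).
    """
    taxa = [f"t{i}" for i in range(n_taxa)]
    # each live node: (member taxa, dict taxon -> distance to this node)
    nodes = [({t}, {t: 0.0}) for t in taxa]
    splits = set()
    dist = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        mi, di = nodes.pop(j)
        mj, dj = nodes.pop(i)
        bi = float(rng.uniform(0.05, 1.0))
        bj = float(rng.uniform(0.05, 1.0))
        for ta, da in di.items():
            for tb, db in dj.items():
                dist[frozenset((ta, tb))] = da + bi + db + bj
        merged = mi | mj
        dvec = {t: d + bi for t, d in di.items()}
        dvec.update({t: d + bj for t, d in dj.items()})
        nodes.append((merged, dvec))
        for side in (mi, mj):
            if 1 < len(side) < n_taxa - 1:
                other = frozenset(taxa) - side
                splits.add(min(frozenset(side), other,
                               key=lambda s: (len(s), tuple(sorted(s)))))
    mat = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            mat[x, y] = mat[y, x] = dist[frozenset((taxa[x], taxa[y]))]
    return taxa, mat, splits
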