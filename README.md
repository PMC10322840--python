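# ksrscan

Comparative sequence analysis of RAF-family kinases and KSR pseudokinases:
kinase-motif fingerprinting, RAF / KSR1-2 / KSR3 family classification,
per-position divergence profiling against a reference kinase, and
homology-guided transposition of pseudokinase-specific residues onto an
acceptor kinase as candidate activating mutations.

## The problem

KSR (Kinase Suppressor of Ras) proteins are catalytically impaired
RAF-related factors that act as scaffolds and allosteric activators of
RAF. The KSR3 family — present in most non-chordate metazoa but lost in
flies, nematodes and chordates — is distinguished from RAF and KSR1/2 by
its domain architecture and by a heavily remodelled kinase domain:

| feature | RAF | KSR1/2 | KSR3 |
|---|---|---|---|
| RAS-binding domain (RBD) | yes | no | no |
| CC-SAM domain | no | yes | no |
| CRD (C1) domain | yes | yes | yes |
| P-loop G-X-G-X-X-G | canonical | canonical | degenerate (E-X-G-X-X-G) |
| VAIK lysine | canonical | canonical | degenerate (VLIQ) |
| HRD catalytic loop | canonical | degenerate (HKD) | absent |
| DFG | canonical | canonical | absent |
| alphaC RKTR (dimer interface) | basic RKTR | basic RKTR | neutral SMIR/SKIR-type |
| beta3-alphaC region | full length | full length | 3 residues shorter |

Because KSR3's natural sequence variants sit exactly where oncogenic
B-RAF mutations map (P-loop, alphaC helix, dimerization interface,
activation segment), transferring KSR3-specific residues onto B-RAF at
the homologous positions predicts activating mutations (e.g. L485R,
K499L, R506S/E, D587K, L588V, the V487 deletion and the QLQA→DIND
alphaC swap). `ksrscan` packages every step of that analysis:

1. **seqio** — FASTA I/O and standard-code translation (1-based residue
   numbering throughout, matching the literature's conventions such as
   B-RAF V600).
2. **align** — affine-gap global/local pairwise alignment (Gotoh,
   BLOSUM62, gap open 11 / extend 1) with bidirectional residue-position
   liftover through alignment columns.
3. **motifs** — window-constrained motif scanning with canonical /
   degenerate / absent grading, CC-SAM/RBD detection by local alignment
   against packaged exemplars, and a per-sequence architecture
   fingerprint.
4. **family** — fingerprint-rule classification (RBD → RAF; CC-SAM →
   KSR1/2; CRD + missing HRD and DFG → KSR3) corroborated by
   neighbor-joining trees with bootstrap supports.
5. **compare** — divergence profiles, donor-specific residue detection,
   mutation transposition with an embedded cancer-mutation lookup, and a
   landmark table guarding against numbering drift.
6. **synthetic_data** — a generator of labelled synthetic RAF/KSR1-2/KSR3
   sequences with exact ground truth (see note below).
7. **cli** — `ksrscan` subcommands orchestrating the stages.

### Synthetic references

The packaged reference sequences are **synthetic stand-ins**, not natural
proteins: they are assembled from an aligned block table so that every
published landmark residue sits at its published coordinate (human B-RAF
G464/G466/G469, K483, L485, RKTR 506–509, D576, D594, V600, …; sea
urchin KSR3 C37/C40, S84/S87, S306/E307, R343, L354, SKIR 361–364,
K443/V444, D452/D455, S586; sea urchin KSR1 R608; hemichordate KSR3
D293/E294, R350, S572; cnidarian KSR3 R390, S618). Motif scans and
alignment liftovers therefore reproduce the literature's coordinate
bookkeeping without downloading any sequence data.

## Worked example

```python
from ksrscan import (reference_records, annotate, classify, pairwise_align,
                     map_position, transpose_mutations, annotate_candidates,
                     MultipleAlignment, reference_msa_rows)

refs = reference_records()
braf, ksr3 = refs["BRAF"], refs["KSR3_PL"]

ann = annotate(ksr3)                 # motif fingerprint of the KSR3 reference
print(ann.kinase_domain)             # (315, 512)
print(ann.hits["VAIK"].matched)      # VLIQ      (degenerate)
print(ann.hits["DFG"].status)        # absent
print(classify(ann).label)           # KSR3

aln = pairwise_align(braf, ksr3)     # coordinate liftover B-RAF -> KSR3
print(map_position(aln, 509))        # 364  (the dimerization arginine)

rows = reference_msa_rows()          # ground-truth master alignment
msa = MultipleAlignment(tuple(rows), tuple(rows.values()))
cands = annotate_candidates(transpose_mutations(
    msa, ["KSR3_PL", "KSR3_SK", "KSR3_NV"], braf, annotate(braf)))
for c in cands[:6]:
    print(c.label, c.kind, c.region, c.known_oncogenic)
```

which prints

```
AVK481>LIQ     segment_swap BETA3              False
L485R          substitution BETA3              False
delV487_A489   deletion     BETA3_ALPHAC_LOOP  False
QLQA493>DIND   segment_swap BETA3_ALPHAC_LOOP  False
K499L          substitution ALPHAC             True
R506S          substitution ALPHAC             True
```

Reading the output: the KSR3 kinase domain spans residues 315–512 with a
degenerate ATP site (VLIQ instead of VAIK) and no catalytic HRD/DFG, so
the classifier calls it KSR3. Lifting B-RAF position 509 through the
pairwise alignment lands on KSR3 R364, the dimerization arginine. The
transposition stage proposes B-RAF mutations carrying KSR3-specific
residues: isolated donor residues become substitutions (L485R, K499L,
R506S — the latter two at positions with reported cancer mutations,
hence the `True` flags), residues aligned to donor gaps become a
deletion (the 3-residue beta3–alphaC shortening starting at V487), and
contiguous donor runs become segment swaps (QLQA→DIND in the alphaC
helix).

The same stages run from a shell:

```sh
ksrscan simulate -n 10 --seed 1 -o sim
ksrscan pipeline sim/synthetic_set.fasta --msa sim/synthetic_set_aligned.fasta \
        --reference RAF_sp00 --replicates 1000 --seed 1 -o run
```

`run/` then holds per-stage reports (annotation TSV/JSON, family calls,
Newick tree with bootstrap supports, divergence profile and region
ranking, candidate-mutation table) plus a manifest; fixed seeds make
reruns byte-identical.

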