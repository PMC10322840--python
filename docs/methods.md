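# Methods

This note documents the models, procedures, parameter choices and known
limitations behind `ksrscan`, in the order the pipeline runs.

## Sequence handling and numbering

Sequences are uppercase strings over the 20 amino acids plus X (protein)
or ACGTN (DNA). Gap characters are rejected outside alignment readers:
sequence and alignment concerns are kept separate on purpose. All
user-facing positions are 1-based inclusive, matching the residue
numbering conventions of the kinase literature (B-RAF V600, KSR3 R364);
any half-open convention is internal only.

Translation uses the standard genetic code, starts at the chosen frame
offset, truncates at the first stop codon and drops a trailing partial
codon. Truncation (rather than an error) is deliberate: cloning
oligonucleotides encode open fragments, and the packaged worked example —
the HA-fusion forward oligonucleotide, whose frame-1 product is three
YPYDVPDYA epitopes followed by the KSR3 N-terminus MQPKEHI — relies on
it. Codons containing N translate to X.

## Pairwise alignment and liftover

Pairwise alignment uses the Gotoh three-state affine-gap model through
`Bio.Align.PairwiseAligner`: BLOSUM62, gap open 11, gap extend 1 (a gap
of length L costs `11 + (L-1)`), end gaps penalized in global mode.
These are the standard protein defaults; they are configurable via
`AlignmentParams`. Among co-optimal tracebacks the aligner's first
enumeration is taken, which is deterministic for fixed inputs, so every
report is bit-reproducible. The test suite checks optimality against an
exhaustive enumeration oracle (maximum over all monotone residue
matchings) for every sequence pair of length ≤ 4 over a four-letter
alphabet.

Residue liftover (`map_position`) walks the alignment columns: a
position maps to its column partner, or to nothing when the partner is a
gap. Liftover through the packaged references reproduces the published
correspondences (B-RAF R509 → KSR3 R364 / KSR1 R608; KSR3 R343 → B-RAF
L485, L354 → K499, S361 → R506), and the 3-residue beta3–alphaC
shortening of KSR3 appears as a contiguous 3-gap run at V487–A489.

## Motif scanning

Each motif is a short positional pattern with designated *anchor*
residues (the three P-loop glycines; all four VAIK positions; H/R/D;
D/F/G; the four RKTR positions) plus a key residue (the VAIK lysine, the
catalytic aspartate, the DFG aspartate, the final dimerization
arginine). Scanning slides the pattern across a window and grades the
best match:

* **canonical** — every pattern position satisfied;
* **degenerate** — at least half of the anchor residues retained (and,
  for the dimerization motif, the key arginine present — this is what
  recognises the neutral SMIR/SKIR variants, which keep only the final
  arginine); the matched substring is reported as the variant
  (ESGSNG, VLIQ, HKD, …);
* **absent** — anything weaker.

The half-of-anchors rule is this package's operationalisation of the
qualitative distinction between "highly divergent" and "simply absent";
no published criterion exists. Candidates are ranked by key-residue
retention, anchor count, exactness, proximity to the expected site and
finally leftmost position — proximity matters because in a pseudokinase
a spurious equally-degenerate match can otherwise displace the variant
at the homologous position.

Windows hang off a single *domain origin* (the estimated P-loop start)
at fixed offsets taken from canonical kinase-domain geometry (VAIK at
+16, dimerization motif at +42, HRD at +110, DFG at +130), with a
half-width of 8 residues that absorbs the small indels between families
(the 3-residue beta3–alphaC deletion, a 1-residue alphaD insertion).
Larger indels would require alignment-mapped windows; that is a known
limitation for distant natural sequences.

Domain anchoring prefers canonical motif hits with priority
HRD > DFG > VAIK > P-loop, where mutually consistent anchors (origins
agreeing within ±10) outvote lone ones. A sequence with no canonical
anchor — exactly the KSR3 situation — is anchored by local alignment
against a packaged synthetic canonical kinase-domain exemplar; if even
that fails (fewer than 30% of exemplar residues aligned) the whole
sequence is used with a low-confidence flag. The domain span runs from
7 residues before the origin to ~30 residues past the activation-segment
end.

Special locators: the NtA acidic pair is the `[STDE][DE]` 2-mer closest
to the domain start within the window 10–20 residues upstream; the
N-terminal 14-3-3 site is the leftmost S-X-X-S in the CRD-to-kinase
linker; the C-terminal 14-3-3 site is the X-S-X-S-E-P match in the
C-terminal third (key = the serine before E-P); the CRD is the relaxed
C1 zinc-finger spacing `H-X(11,13)-C-X2-C-X(12,15)-C-X2-C` in the
N-terminal half; ERK feedback sites are strict P-X-[ST]-P matches lying
entirely outside the kinase domain (no published consensus is given for
these sites; the strict pattern is our choice). CC-SAM and RBD are
detected by local alignment against packaged exemplars with a threshold
of half the exemplar self-score — far above the empirical maximum over
100 shuffled-exemplar alignments (checked in the test suite).

Region table: PLOOP = the P-loop match; BETA3 = VAIK ± 3; ALPHAC = the
window from 12 before to 8 past the dimerization-motif start; DIF = the
dimerization arginine ± 5; CATLOOP = the HRD window (8 residues); AS =
DFG through DFG+30; BETA7_BETA8 = the residues between catalytic loop
and DFG (the region carrying D587/L588, which *follows* the catalytic
loop); NTA = six residues ending at the acidic pair; CRD and CC_SAM from
their matches. For degenerate or absent motifs the expected window
position stands in for the missing hit.

## Family classification and trees

Classification is a pure function of the fingerprint with the rule
precedence the discriminating domains impose: RBD → RAF; else CC-SAM →
KSR1/2; else CRD with *both* HRD and DFG missing → KSR3; anything else
(including an RBD+CC-SAM conflict) → UNKNOWN. UNKNOWN is preferred over
guessing. A degenerate motif counts as *present* for the HRD/DFG rules —
KSR1's HKD keeps it out of the KSR3 bin even if its CC-SAM were missed.

Distances are p-distances over shared residue columns (pairwise
deletion), optionally Poisson-corrected (−ln(1−p)). Trees are standard
neighbor joining (via scikit-bio) with negative branch lengths clamped
to zero; NJ is a deliberate distance-based approximation and likelihood
inference is out of scope. The test suite checks NJ against an
independent agglomerative tree simulator: additive matrices of up to six
taxa always return the generating topology. Bootstrap resamples
alignment columns with replacement (default 1000 replicates, seeded),
rebuilds NJ per replicate and maps bipartition frequencies onto the
full-data tree as percentage supports (majority-rule mapping; the
consensus cutoff convention is 50%).

## Divergence profiling and transposition

The divergence profile reports, for each column where the reference has
a residue, the fraction of set sequences differing from it; set-sequence
gaps count as divergent (configurable — no published rule exists), and
reference-gap columns are skipped. Region summaries average the profile
over the named regions and rank them.

Donor-specific residues are columns where ≥ 80% (default) of the donors
share one residue that differs from the acceptor's. Transposition turns
them into candidates within the regions of interest (beta3 through the
activation segment by default; the P-loop is excluded because P-loop
positions were not transposed in the motivating analysis): isolated
positions become substitutions, contiguous runs of ≥ 3 become one
segment swap carrying the donor consensus, and acceptor residues aligned
to donor gaps become one deletion candidate per contiguous run (an
in-frame run deletion, e.g. the V487–A489 run, rather than three
single-residue deletions). Labels use both compact (L485R) and
HGVS-style (p.Leu485Arg) notation. The QLQA→DIND candidate's note
records the DIND/DLND discrepancy between text and primer sources
verbatim instead of resolving it.

The known-oncogenic lookup is an embedded static table of B-RAF
cancer-mutation positions (464, 468, 469, 485, 499, 506, 588, 594, 597,
600), variant-aware where specific variants are reported: L485F/W/S are
flagged while L485R and R506E — explicitly reported as never described —
are not. No external database is ever queried; candidates on non-B-RAF
acceptors return an undetermined flag.

The landmark table packages every cited residue coordinate and validates
residue letters against loaded sequences; when one uniform shift fixes
all failures for a sequence, that shift is suggested (the table also
carries a configurable global offset, in case a reference's translated
ORF numbering is off by a constant).

## Synthetic data: what it emulates and what it does not

All five reference templates (B-RAF-like, KSR1-like and three KSR3
species flavours) are assembled from a master table of aligned blocks —
shared kinase-domain scaffold, family-specific motif blocks,
family-specific linkers — so the generator knows the true multiple
alignment and every landmark position of everything it emits, and
validates both at construction time. Block lengths are solved so that
each landmark sits at its published coordinate; the indel bookkeeping
implied by those coordinates (the 3-residue beta3–alphaC deletion
between KSR3 343 and 354, a 1-residue insertion before beta7–beta8) is
encoded explicitly.

Linker filler is deterministic pseudo-random sequence over a 12-letter
alphabet that deliberately omits G, C, P, S, D, E, H and R, so no
spurious P-loop, CRD pattern, feedback site, acidic pair, serine pair or
HRD/DFG can arise outside the intended sites; the construction asserts
motif uniqueness. The noise model substitutes, independently per site
with the given rate, a uniformly random different residue at *mutable*
positions (linker filler and accessory-domain sequence); motif cores and
landmark residues are protected unless `scramble_motifs` is set. Indels
(rate-driven single-residue insertions/deletions) are confined to linker
blocks, so landmark identities survive with shifted positions; the
ground-truth alignment row is only emitted when no indels were applied.
The divergence study set additionally concentrates substitutions in the
P-loop, alphaC and activation-segment columns (default hotspot rate
0.35 against 0.02 elsewhere), emulating the observed clustering of
KSR3 divergence, and is restricted to the kinase-region columns where a
divergence profile against a kinase is meaningful.

What passing tests on this material shows: the scanning, grading,
classification, liftover and transposition logic is correct on sequences
whose motif grammar and coordinate layout match the published
architectures, including under 5% substitution noise and linker indels.
What it does not show: performance on natural sequences with real
compositional bias, long heterogeneous linkers, or indels inside the
kinase domain larger than the window half-width; CC-SAM/RBD detection
thresholds against natural domain families; and any phylogenetic realism
beyond within-family similarity exceeding between-family similarity (the
noise model is not a substitution model).

## Problem sizes and determinism

Default study sizes are chosen at desk scale: classifier recovery is
measured on 90 sequences at zero noise and 300 at 5% noise; bootstrap
support on 30 sequences × 200 replicates; the divergence study on 19
KSR3 variants against the reference, mirroring a 19-sequence comparison
set. Every stochastic step takes an explicit integer seed and a single
NumPy generator stream; identical configuration yields byte-identical
outputs, which the CLI manifest (config hash + seed) makes checkable.

## Known limitations

* Motif windows are offset-based, not alignment-mapped; very divergent
  natural kinases with large domain indels may need wider windows.
* The NtA locator is pattern-based, not liftover-based: the published
  equivalence of the KSR3 N-terminal serines with "S259" follows C-RAF
  numbering rather than B-RAF, so no B-RAF anchor is used for it (the
  same applies to "T491" of the activation segment).
* NJ supports are corroboration, not inference: no likelihood model, no
  rooting, no dating.
* The oncogenic lookup is a static snapshot compiled from cited
  positions; it is not a cancer-genomics resource.
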