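# Methods

This note records the models, conventions and numerical choices behind
each analysis, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinate and strand conventions

All coordinates are 1-based inclusive on the majority (J) strand, the
GenBank convention. A feature spanning the origin of the circle is
encoded with `end < start`; its length is `L − start + 1 + end`. Strand
is `J` or `N`; the coding-strand sequence of an N-strand feature is the
reverse complement of its J-strand slice. The canonical gene vocabulary
is the 13 protein-coding genes (atp6, atp8, cox1–3, cob, nad1–6, nad4L),
22 tRNAs (`trnX`, with trnL1/trnL2 and trnS1/trnS2 distinguished by
anticodon), rrnS, rrnL and the control region `CR`; common aliases (COI,
ND5, CytB, l-rRNA, A+T-rich region …) are normalised on input.
Duplicated genes keep one name with `copy_index` 1..k. Ambiguity code N
is accepted in sequences and excluded from base counts (reported
separately) and pairwise distances.

## Composition and skew

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C); when a denominator is zero
the skew is reported as undefined (`None`) rather than raising. Skews are
computed on the J strand for whole genomes and on the coding strand for
per-gene reports. The genetic code is fixed to the invertebrate
mitochondrial code (NCBI table 5) throughout; its synonymous-family sizes
(e.g. the 8-codon serine family including AGA/AGG) define every RSCU
denominator. Codons are read in frame from position 1; a trailing partial
codon — the incomplete T/TA stop completed by polyadenylation in vivo —
is excluded from codon counts, and full stop codons are tallied
separately from the 62 sense codons. The RSCU of an unobserved codon is
0; within every synonymous family with nonzero total the mean RSCU is 1
by construction.

## Gene orders and rearrangement

A gene order is a signed circular permutation (sign = strand). The
oriented adjacency x→y is identified with −y→−x, so breakpoint distance
— adjacencies of one order absent from the other — is invariant under
rotation and under reflection with sign flip, and is symmetric for equal
label sets. It is not a metric on signed circular orders, and no triangle
inequality is asserted. Conserved blocks are maximal circular runs whose
internal adjacencies are shared; a gene whose adjacencies changed on both
sides is reported as displaced (the signature of a single-gene
translocation, e.g. trnH between the two published annotations of the
same species). Duplicated genes are collapsed (and flagged) before
comparison: adjacency analysis is ill-defined on multisets. The control
region is excluded from orders by default since it is not a gene. Three
reference orders ship as data files rather than code: the putative
ancestral insect order, the shared planthopper (delphacid) order — which
differs from the ancestral one exactly in the trnC–trnW and
nad6–trnP–trnT neighbourhoods — and the prior small-brown-planthopper
annotation with trnH between nad4L and nad6. Inversion/sorting-by-
reversals distances and gene-order phylogenetics are out of scope.

## tRNA cloverleaf folding

Folding is a deterministic layout-constrained search, not free-energy
minimisation: the target is classification of arm completeness, not
thermodynamics. The layout in 5'→3' order is acceptor stem 5' side, D
window, anticodon arm (stem, 7-nt loop with the anticodon centred, stem),
variable region, T window, acceptor stem 3' side. Allowed pairs are
Watson–Crick plus G:U wobble (configurable). Stem targets/minima are
acceptor 7/5, D 3/2, anticodon 5/4, T 4/2; loops are ≥ 3 nt (D loop ≤ 11,
T loop ≤ 9) and the variable region ≤ 23 nt. The search anchors the
anticodon arm (at the supplied anticodon, at anticodons decoding a given
amino acid, or freely), then maximises pairs in the acceptor, D and T
stems within the windows the anchor leaves; stems below their minimum are
reported `loop_only` (or `absent` when the window cannot hold a loop).
Ties resolve by the documented lexicographic key: more total pairs,
longer acceptor stem, smaller variable region, leftmost anchor, longer
anticodon stem, then leftmost/tightest D and T placements — so the result
is a pure function of (sequence, parameters). The unit tests hold this
search to an independently coded exhaustive enumeration of the same
layout space. Classification: `canonical` iff all four arms are full;
`dhu_loop_only` / `t_loop_only` when exactly that arm fails (the DHU
case mirrors the serine tRNAs of these genomes); otherwise `degenerate`.
"Weak" stems are not given a special category; consumers can inspect stem
lengths and pair counts. Pseudoknots and covariance-model searches are
out of scope.

## Control-region repeats

Tandem arrays are found by a periodicity scan: for each candidate period
p the sequence is matched against itself shifted by p, windows of p
positions with ≥ `min_identity` matches seed candidate arrays, and each
seed is refined copy-by-copy against a per-column majority consensus.
Because a seed may sit mid-copy, all p phase shifts are refined and the
phase maximising exact (then ≤ 1-mismatch) copies wins — the true
copy-boundary phase splits no degenerate copy across two windows. Copies
are walked outward while identity to the anchor unit stays ≥ 0.5;
boundary copies below `min_identity − 0.1` are trimmed as flank
absorption, so genuinely degenerate copies (including boundary ones)
stay inside the array flagged incomplete, as in the published arrays
(copy 2 of 55, and copies 3/14/35 of 35). A copy is complete iff its
identity to the consensus is ≥ `min_identity` and its length ≥ 0.8 p.
Overlapping candidates are resolved longest-array-first, except that a
candidate whose period divides an accepted array's period and covers
≥ 80 % of its span replaces it (primitive-unit preference: an array
detectable at p and 2p reports p). Arrays whose consensus is a
homopolymer are rejected — those are poly runs, reported separately.
Defaults (`min_period` 10, `max_period` 50, `min_copies` 3 complete
copies, `min_identity` 0.8) comfortably detect 21-bp units at tens of
copies while 5 kb of uniform random sequence yields nothing (verified
over 20 seeds). The consensus reports the majority base at the variable
21st position of the brown-planthopper unit; per-column variability is
available via `column_variability`. Repeat-unit comparison minimises
Levenshtein distance (via edlib) over all cyclic rotations and both
strands; the two published planthopper units differ by ≤ 2 under this
measure. Trailing partial copies are not modelled: the generator plants
whole copies, and array spans tile exactly.

## Population analyses

Variable sites are columns with ≥ 2 non-ambiguous alleles. Haplotypes
collapse identical signatures over the variable sites and are numbered by
descending count with first-occurrence tie-breaks. The haplotype network
is the union of all minimum spanning trees on Hamming distances (an edge
joins the network iff its endpoints lie in different components of the
forest built from strictly smaller distances), so equally parsimonious
connections are all retained; median-joining's inferred intermediate
haplotypes (ε > 0) are deliberately not implemented — the observed
topology here is reproducible without them. Nucleotide diversity π is the
mean pairwise p-distance with ambiguous positions excluded per pair.
Mutation effects use fragment-relative coordinates: in a coding segment
whose frame starts `frame_offset` bases after the segment start, position
p lies in codon `(p − start − offset)//3 + 1`; the reference and mutated
codons are translated under the invertebrate code. The packaged 642-bp
survey fragment places the nad5 frame at position 1, which maps positions
277 and 391 to codons 93 and 131 (M93L, D131N). Two-genome divergence
compares equal-length genes position-wise on the coding strand —
length-variant genes are excluded with an explicit reason rather than
aligned silently — and indel events are maximal gap runs of a supplied
pairwise alignment.

## The synthetic-data generator

`make_mitogenome` realises a spec exactly: the packaged delphacid gene
order; per-gene lengths close to the published ones (rrnS 747 bp, rrnL
1219 bp, atp8 99 bp, total ≈ 16.9 kb); configured start codons (ATG/ATT,
plus ATA for nad3 and atp6) and stops, with incomplete T stops planted in
cox1, cox3, atp6 and nad5; tRNAs built to prescribed arm configurations
(trnS1 DHU-loop-only by default, optional trnC triplication); and a
control region with the 21-bp repeat array (55 copies, copy 2 degenerate,
variable last base), a 23-bp poly-T run insulated by non-T separators,
and flanks sized to give the published 2429-bp control-region length.
Base composition targets A 0.42, T 0.35, G 0.094, C 0.136 (A+T = 0.77):
bases are sampled from that distribution, then a repair pass adjusts only
non-coding fill and third positions of four-fold degenerate codons until
the realised A+T content is within 0.002 of target, so start/stop codons,
tRNA stems and the repeat array are never touched; an unreachable target
raises. `make_trna_seq` assembles explicit stems (G/C-biased pairs) and
poly-A loops — poly-A windows cannot base-pair, which guarantees a
loop-only arm — and verifies by folding, retrying with derived seeds
before declaring a configuration unsatisfiable. `make_population` plants
exact haplotype counts: 178/93/18 majors separated by the two
nonsynonymous nad5 mutations, plus 7 doubleton and 6 singleton minor
haplotypes over 12 silent third-position sites (one minor haplotype
carries an additional nonsynonymous change, one uses the single
intergenic site), i.e. 309 individuals, 16 haplotypes, 15 variable nad5
sites and 1 intergenic site. `mutate_genome` plants exact per-gene
substitution counts (uniform positions without replacement) and
start/end indels, returning the derived genome, its shifted annotations
and the implied alignment; genes containing indels change length and are
therefore excluded from divergence with a reason, mirroring the published
treatment of the length-variant genes.

What the generator does **not** emulate: codon-usage bias beyond base
composition (so published codon totals and amino-acid percentages are not
reproduction targets), secondary-structure constraints in rRNAs,
transition/transversion bias, sequencing error, heteroplasmy, or
recombination. Passing tests therefore demonstrate correctness of the
*operations* on data with the stated structure, not distributional
realism of real planthopper sequences.

## Problem sizes and determinism

All randomness flows through explicit integer seeds into
`numpy.random.default_rng`; identical specs give byte-identical outputs.
The test suite and the acceptance script use one ~17 kb genome per
scenario, 309-sequence populations, repeat arrays up to 60 copies, and
brute-force oracles on signed permutations of ≤ 6 labels and tRNA-length
sequences of ≤ 64 nt — sizes at which the exhaustive oracles are exact
and the whole suite runs in well under a minute.

## Known limitations

- The cloverleaf search reports one optimal layout; near-optimal
  alternative foldings are not enumerated.
- Tandem-repeat detection assumes arrays of a primitive unit ≥ 10 bp by
  default; microsatellites below `min_period` are invisible, and nested
  arrays (an array inside another array's unit) are resolved greedily.
- Divergence requires equal-length genes; users must pre-align
  length-variant genes themselves if they want per-site rates for them.
- GenBank parsing supports single-record files with simple or
  origin-spanning compound locations only.
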