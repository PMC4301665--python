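# Methods

This note documents the models, conventions and numerical choices behind
`orthodiverge`, in the order the pipeline applies them.

## Sequence model and assembly statistics

Transcripts are nucleotide strings over {A,C,G,T,N}; RNA input is
normalised (U→T, upper-case) at parse time, and IUPAC ambiguity codes other
than N are rejected because every downstream classifier (degeneracy, CpG,
codon counting) assumes an unambiguous base or N. N50/N90 follow the
standard assembly-stats convention: sort lengths descending, take the
smallest prefix whose cumulative length reaches 50% (90%) of the total, and
report that prefix's shortest member. GC percentages exclude N from the
denominator and are reported on the 0–100 scale, lengths in bp, throughout.

## ORF annotation

ORFs are ATG→stop on both strands; the CDS is the top-ranked ORF, ranked by
length (longest first, ties: + strand, then smaller start) — the standard
transcript-CDS heuristic when no protein evidence is available.
3'-incomplete ORFs (no stop before the transcript end, common in
pyrosequencing assemblies) are accepted and clipped to the last full codon.
The stop codon is kept inside the CDS interval for bookkeeping but stripped
before any codon-level analysis. Transcripts with no ORF ≥ 150 nt (default,
matching the 150-bp pair filter) are flagged non-coding and excluded from
CDS analyses. A CDS-coordinate TSV can override prediction. UTR prediction
has no independent evidence here: the partition is deterministic from the
ORF call.

## Orthology

BLAST is replaced by a self-contained, deterministic equivalent: candidate
pairs must share an 11-mer (nucleotide level, both strands) or a protein
4-mer over six-frame translations (translated level); candidates are scored
with local alignment (match 2 / mismatch −3 / gap −5,−2 at the nucleotide
level, BLOSUM62 / −11,−1 at the protein level, via biopython's
PairwiseAligner). Best hits break ties by score, then matched length, then
lexicographic subject id, so reruns are identical. A pair is emitted when
each member is the other's best hit and the aligned continuous region
covers ≥ 50% of the query in each direction; it is one-to-one only when
neither member is the best hit of any other query. Queries with no
nucleotide-level pair are retried at the translated level after dropping
those < 250 bp (logged and counted "too short"). With exactly two species
and pairwise data, speciation-node detection by species overlap reduces to
reciprocal best hit, which is what is implemented; gene-tree approaches are
out of scope.

## Alignment and site classification

CDS pairs are aligned through their protein translations (global, BLOSUM62)
and back-mapped to nucleotides, so indels are whole codons at codon
boundaries; gap columns are then removed, mirroring the usual align-then-
trim workflow. UTRs are aligned directly with affine gaps; their gap
columns are retained but excluded from every statistic via the per-column
comparable flag (no gap and no N in either sequence; CDS columns further
require both full codons readable).

Degeneracy is evaluated against both codon contexts: a column is *4d* iff
it is a third position whose two-base prefix is identical across the pair
and is one of the eight fourfold families; *nd* iff every sense
single-nucleotide change at that position is nonsynonymous in both codons
(changes to stops are excluded from consideration, the usual convention).
Columns whose two contexts disagree fall into *other* rather than being
double-counted, so nd + 4d + other exactly equals the comparable CDS
columns.

CpG context has no ancestral reference in a two-species comparison, so a
column is CpG when the base participates in a CG dinucleotide in **either**
extant sequence (symmetric; an intersection mode is available as a switch).
Boundary positions use only the available neighbour; the lookup is done in
the full ungapped transcript, so a CDS base next to a UTR base sees its
real neighbour.

## Divergence tables

Percent difference per (region × context) cell is reported in two modes.
`per_pair` (default): unweighted mean of per-pair percentages, with the
dispersion column being the standard error of that mean across pairs
(labelled explicitly, since "SE" is ambiguous in this literature); pairs
contributing zero comparable columns to a cell are excluded from that
cell's mean, not imputed as zero. `pooled`: 100·Σdiffs/Σcompared. Compared
kb, ts/tv counts, GC% and CpG% are always pooled, which makes the identity
`all = CpG + non-CpG` hold exactly for counts in every region; the
`per_pair` ALL row is deliberately *not* the site-weighted average of its
CpG/non-CpG rows — that non-additivity is a property of per-pair averaging
and is why both modes are provided.

## Ka/Ks

**NG86.** Per sense codon and position, the synonymous site fraction is the
fraction of sense single-nucleotide neighbours that are synonymous (stop
neighbours leave the denominator but the position still counts one site, so
s + n = 3 per codon). S and N are averaged over the two sequences.
Differences are averaged over all minimal mutational pathways between the
two codons; pathways through stop codons are discarded, and in the rare
case that every pathway is blocked the counting falls back to the
stop-inclusive convention and flags the pair. Proportions pS = Sd/S and
pN = Nd/N are corrected with Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3);
p ≥ 3/4 is reported as saturated (the pair is excluded from summaries
rather than silently coerced). This implementation is checked exactly
against an independent brute-force enumeration oracle in the test suite.

**YN.** The κ- and composition-aware approximate estimator follows the
structure of the Yang–Nielsen approximate method: κ is estimated from
fourfold-degenerate and non-degenerate positions with the K80 correction
(per-class κ = 2A/B, combined weighted by site counts); synonymous site
fractions weight each neighbour by κ (transitions) and by the F3×4
position-specific frequency of the target base estimated from both
sequences; pathway-averaged differences are split into transitions and
transversions, and Ka and Ks are each corrected with the K80 two-parameter
formula. This is a faithful member of the same approximate-method family
rather than a line-by-line port of any particular implementation; it is
validated by two independent routes — it reduces to NG86 (S, N equal to
within well under 2%) at κ = 1 with uniform composition, and it recovers
simulated ω ∈ {0.2, 1, 2} with median error ≈ 1% at 500 codons (NG86 on the
same data is biased low by ~12% under κ = 2, the expected direction). When
κ is not estimable (no informative differences) the estimator falls back to
NG86 counting and flags the result.

**Significance and binning.** The Fisher exact test uses the 2×2 table
[[Sd, S−Sd], [Nd, N−Nd]] with round-half-up integer cells, two-sided.
ω bins are right-closed: (>2, (1,2], (0.5,1], ≤0.5); pairs with Ks = 0 are
reported separately (ω is emitted as an explicit +inf sentinel in TSV when
Ka > 0, never silently placed in a bin).

**Sliding windows.** Windows (default 57 bp, step 6 bp, both multiples of
3) are positioned on the gap-column-removed CDS alignment, 0-based
half-open; NG86 is the default within windows (cheap and oracle-backed).
A 300-bp alignment yields ⌊(300−57)/6⌋+1 = 41 windows; shorter-than-window
alignments produce a single whole-alignment window with a warning. Windows
with ω > 1 (including Ks = 0, Ka > 0) are flagged as candidate positively
selected loci. With step = window length the raw window counts sum exactly
to the whole-gene counts.

## Synthetic data generator

Each gene draws an ancestral transcript — i.i.d. UTRs and a CDS of
ATG + stop-free codons + stop at the configured base frequencies — and
evolves two independent branches. Proposals per branch are
Poisson(t/2 · length); each proposal picks a site and target base with
probability ∝ π_target · κ^[transition] · cpg_mult^[CpG-context transition],
with CpG context evaluated on the current sequence state (hypermutability
is context-dependent, not ancestral). Stop-creating proposals in the CDS
are rejected. Selection is acceptance thinning: nonsynonymous proposals are
accepted with probability min(1, ω) and synonymous ones with min(1, 1/ω),
so the realized nonsynonymous/synonymous rate ratio equals ω for any
ω ≥ 0 — a pure min(1, ω) rule would make every ω ≥ 1 indistinguishable
from neutrality, so the symmetric rule is used. Rejected proposals are
consumed, so under this convention the realized synonymous divergence is
≈ t for ω ≤ 1 and ≈ t/ω above (the ω = 2 recovery experiments therefore
use t = 0.1·max(1, ω) to hold Ks near 0.1). The CDS start and stop codons
are frozen so the true reading frame stays discoverable by the ORF
annotator. Every applied substitution is tallied (region, ts/tv, CpG
context, syn/nonsyn) in a truth object that is recountable from the emitted
sequences. Same seed ⇒ byte-identical FASTA.

Defaults are chosen to resemble a closely related aphid ortholog set:
185-codon CDS, 262/283-bp UTRs, AT-rich composition
(A/C/G/T ≈ 0.30/0.20/0.20/0.30), κ = 2, ω = 0.2, t = 0.2, cpg_mult = 1
(no CpG hypermutability by default — insect methylation is weak and the
multiplier is a parameter, not an assumption), 10 decoys, no paralogs.

What the generator does *not* emulate: indels (orthologs are colinear, so
alignment recovery is not stressed), rate heterogeneity across sites or
genes, assembly artefacts, chimeric transcripts, and sequencing error.
Passing tests therefore demonstrate correctness of the statistics and
filters under the stated model, not robustness to misassembly.

## Problem sizes and determinism

The test suite and the acceptance script use: 200 simulated pairs × 500
codons per ω value for parameter recovery; 50 × 2000-bp UTR pairs for ts/tv
recovery; 20 replicates × 10 × 2000 bp for the CpG effect; 100 replicates
of the window-localization experiment; and a 50-gene + 10-decoy set for
orthology fidelity — sizes at which the stochastic checks have comfortable
margins while a full run stays around a minute. All randomness flows
through numpy Generators seeded from explicit seeds; reruns are
bit-identical.

## Known limitations

* The RBH aligner is a seeded Smith–Waterman, not BLAST: scores and
  borderline hits will differ from BLAST-based workflows, though the
  orthology logic (mutual best, 50% coverage, 250-bp translation floor) is
  the same.
* The YN estimator is an approximate method; for publication-grade single
  genes a likelihood codon model is preferable. Ks = 0 and saturated pairs
  are reported, not estimated.
* Degeneracy classes require agreement of both codon contexts, so nd/4d
  totals are conservative (they undercount relative to single-sequence
  classification).
* UTR divergence is an uncorrected proportion; no multiple-hit correction
  is applied outside the CDS.
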