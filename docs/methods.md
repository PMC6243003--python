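# Methods

This note documents the models, parameters and design decisions behind
familyscope — what each stage assumes, which knobs matter, what the
synthetic data does and does not emulate, and where the numerical
behavior is pinned by choice rather than by necessity.

## Domain grammar

A WRKY domain is detected as a heptapeptide anchor plus a downstream zinc
finger. The heptapeptide set is closed: `WRKYGQK` and the four variants
observed across the family (`WRKYGKK`, `WRKYGEK`, `WKKYGQK`, `SRKYGQK`).
Matching is exact and non-overlapping, resolved leftmost-first; `X` never
matches. Arbitrary 7-mers are deliberately not treated as degenerate
domains — in this family's annotation practice, other substitutions are
non-domains, and the set is extensible via an argument for other taxa.

The zinc finger is the pattern `C X{n1} C X{n2} H X (H|C)` with
n1 ∈ [4, 7] and n2 ∈ [21, 30]. These ranges cover every signature observed
in the two Vigna families (including the rare CX6 and CX30 outliers) with
no slack, which keeps the false-positive surface small; both ranges are
config-overridable. The first terminal residue must be histidine: H·X·H
defines a C2H2 finger, H·X·C a C2HC finger, and C·X·C candidates are
rejected. When several fingers could start at one cysteine, the smallest
n1 and then the smallest n2 wins, i.e. the most compact finger.

Pairing windows are a design decision, not a family fact: a heptapeptide
claims the first finger starting within 90 residues downstream (domains
are "around 60" residues; 90 tolerates the CX30 outlier), and an orphan
finger becomes a truncated domain only if no heptapeptide ends within 30
residues upstream. Unpaired heptapeptides are kept as
`missing_zinc_finger` domains, mirroring how family tables keep truncated
members. With two or more domains the first is the NTWD and the others
CTWDs.

## Classification

The grammar decides what it can: two domains → Group I (kept even when one
member domain is truncated, as family tables do); a single C2HC finger →
Group III; a single C2H2 finger with n1 = 4 → IIc. The four remaining
subgroups (IIa, IIb, IId, IIe) share the single-C2H2/n1 ≥ 5 signature and
are genuinely inseparable by grammar, so the call goes to the nearest
labeled reference domain under the p-distance after pairwise alignment —
the in-silico analogue of placing queries on a reference tree. Without
references the record is labeled `II-unresolved` rather than guessed.
Heptapeptide-only truncations are likewise unresolvable by grammar alone
and fall back to references when available.

Isoforms are collapsed per locus (protein id = mRNA id; gene id strips the
trailing `.k` suffix): the longest protein represents the gene, ties going
to the lowest suffix. Identical sequences at *different* loci are kept and
cross-flagged `redundant_with`. Percentages are computed as
100·count/total and rounded half-up to one decimal (the combined IIa+IIb
share to the nearest integer); half-up is pinned because it reproduces the
published one-decimal values exactly (e.g. 15/84 → 17.9, 7/85 → 8.2).

## Protein properties

Molecular weight is the sum of average residue masses plus one water
(18.015 Da); residue masses derive from Biopython's average amino-acid
masses. `X` contributes a configurable 110.0 Da with a warning. The
isoelectric point solves net charge = 0 by bisection on pH ∈ [0, 14] to
|charge| < 1e-4, with Henderson–Hasselbalch terms for the termini and
D/E/C/Y/H/K/R. The pKa table (N-term 7.5, C-term 3.55, D 4.05, E 4.45,
C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0) is a Bjellqvist-style convention
declared as a constant so results are pinned; web tools ship their own
internal tables, so exact agreement with any particular service is not a
goal and published pI ranges are not used as test oracles.

## Gene structure and conserved introns

Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at the parse boundary (gffutils, in-memory db).
Introns are the gaps between consecutive CDS segments in transcription
order (minus-strand models walk exons 3'→5' genomically), and the phase is
the cumulative upstream CDS length mod 3, counted from the CDS ATG — UTRs
and any transcription start site are outside the model.

Two conserved domain introns are typed. R-type: phase 2, interrupting a
codon between the heptapeptide end and the finger's first cysteine, with
the last complete upstream codon encoding arginine ("exactly after the R"
is operationalized at codon granularity; no base-level rule exists).
V-type: phase 0 immediately before the residue at c2+6 — the sixth residue
after the finger's second cysteine — which must be valine unless
`lenient_v` is set (the position, not the residue, is the conserved
feature; strict V is the default because it is what the synthetic truth
plants). Everything else is `other`.

## Duplication calling

Distances are start-to-start, which is robust to unannotated UTRs (the
convention is stated because surveys rarely define it). A cluster is a
maximal chain of family genes with consecutive gaps ≤ 200 kb on one
sequence (singletons dropped); a tandem pair lies within 100 kb with at
most 3 intervening genes ("zero or few spacer genes" quantified as ≤3, the
largest spacer count in the motivating survey's own examples); both
windows are parameters. Segmental pairs are paralogs on different
sequences (or > cluster-window apart on one) exceeding 70% alignment
identity and 60% coverage of the longer protein — thresholds invented for
this artifact, chosen to separate planted duplicates (100% identity) from
same-subgroup background (~50%), and validated only against synthetic
truth. A fast edit-distance bound (edlib) prefilters candidate pairs
before the exact aligner runs.

## Phylogeny

The aligner is global Needleman–Wunsch with linear gap cost and a
transparent scoring triple (match +1, mismatch −1, gap −2); traceback ties
are broken diagonal → up → left so every alignment is unique and
reproducible. Reproducing any specific external aligner's output is a
non-goal. The multiple alignment is center-star: the center maximizes
summed pairwise scores (computed by a vectorized score-only recurrence
that provably equals the DP score), and merges follow "once a gap, always
a gap". Distances are p-distances over columns where neither row is
gapped; a pair with no comparable columns is an error, except inside the
bootstrap where it is assigned the maximum distance 1.0 (a resample can
drop every shared column of a gappy pair, and aborting a replicate would
bias supports).

Neighbor joining is the standard Saitou–Nei agglomeration; Q-matrix ties
break on the smallest index pair, negative branch lengths are clamped to
zero with the original values recorded on the tree, and an all-zero
matrix yields an arbitrary resolved topology flagged `degenerate`. On any
additive matrix the implementation reproduces the generating tree's
topology and path lengths to well below 1e-9 (tested on random 6-taxon
trees and cross-checked topologically against dendropy's NJ). The
bootstrap resamples alignment columns with replacement from a single
seeded NumPy generator; support is the percentage of replicates containing
each original internal bipartition. The `bootstrap()` default is 1000
replicates; the pipeline-level default is 0 (tree without supports)
because a thousand NJ rebuilds on a family-sized matrix is a
figure-making step, opt-in via `bootstrap_replicates`.

Nearest-reference queries return the label of the reference minimizing
p-distance after pairwise alignment, with the runner-up margin; ties go to
the lexicographically smallest reference id with margin 0.

## Promoters

The promoter is the 1500 bases immediately 5' of the translation start on
the coding strand (reverse-complemented for minus-strand genes), truncated
with a flag at contig edges. The start codon — not a transcription start
site — is the zero reference because CDS-only gene models carry no TSS.
Offsets count backwards: −1 is the base abutting the ATG, and each hit is
anchored at its 5'-most coordinate in the plus-strand frame. Scanning is
exact IUPAC matching on both strands with all overlapping occurrences
reported; deduplication is left to downstream consumers. The bundled
element dictionary (ABRELATERD1, DPBFCOREDCDC3, DRECRTCOREAT, ERELEE4,
PREATPRODH, W-box cores, MYBCORE, GT1CONSENSUS) carries published
PLACE-style consensi; it is replaceable input, not ground truth, and any
TSV of name/IUPAC pairs can be supplied instead.

## Expression

A gene is expressed when FPKM ≥ 0.5 in at least one sample; the threshold
comparison is inclusive (the convention does not state strictness, and a
boundary value "reaching the threshold" reads as detected). All-zero rows
are reported separately as not-detected rather than merely unexpressed.
The plotting transform is log2(FPKM+1); the pseudocount keeps zeros at
zero. Read processing and FPKM estimation are out of scope — the matrix is
an input.

## Synthetic data: what it emulates, and what it does not

The generator materializes a complete input bundle (genome FASTA, proteome
FASTA, GFF3 with populated phase column, element dictionary, FPKM table,
labeled reference domains) plus a truth table, from a single seed;
identical specs produce byte-identical files.

Exactness is engineered, not hoped for:

- Protein filler excludes C, H and Y. Fingers need C and H and every
  heptapeptide variant contains Y, so planted motifs are the only grammar
  matches. Decoy filler keeps C but excludes H and Y, so decoys look
  protein-like yet can never contain a domain.
- Each subgroup draws one maximum-length spacer filler per spec; every
  signature variant (CX5CX30, CX6, CX4CX22) slices it, so variants differ
  from their subgroup's reference domain by indels only and
  nearest-reference classification is unambiguous. A 6-residue subgroup
  marker in the n2 spacer separates the grammar-ambiguous subgroups.
  Genes add at most two point substitutions at designated filler sites.
- Promoter windows are random sequence repaired position-by-position until
  the dictionary scan returns exactly the planted hits on both strands
  (degenerate positions of planted elements are re-realized if a spurious
  match cannot be broken outside them).
- Regular genes sit 210 kb apart — beyond the 200 kb cluster window — so
  the only clusters/tandem pairs/segmental blocks are the declared
  islands; truth membership is declared in the plan, never computed by the
  caller's own algorithm.
- CDSs are back-translated with uniformly random synonymous codons;
  introns are `GT…AG` with random interiors; R-/V-type introns are placed
  at the codon positions the typing rules define; isoforms truncate the
  last exon in-frame; segmental copies reuse the source protein verbatim.

The default study (the standard conditions used by the acceptance script)
plants 200 WRKY genes and 100 decoys on eight chromosomes plus one
scaffold, with about one gene in three on the minus strand, tandem pairs
at 30 kb/0 spacers, 80 kb/3 spacers and 20 kb/1 spacer, a three-gene
180 kb-chained cluster, a 120 kb cluster-but-not-tandem pair, and a
two-gene segmental block copied across chromosomes. FPKM vectors cycle
through expressed / boundary (0.5, 0.49) / all-zero patterns over four
samples.

What passing these tests shows: the pipeline's logic is exact on inputs
satisfying its assumptions. What it does not show: robustness to real
genomes — no sequencing noise, no codon bias, no indel/SNP variation, no
pseudogenes, no alternative splicing beyond 3' truncation, no ambiguous
domains near the grammar boundaries, and filler alphabets that exclude by
construction the residues that make real detection hard. Real-data
performance depends on the grammar's biological completeness, which the
synthetic study deliberately does not probe.

## Problem sizes and determinism

The test suite runs the full pipeline on a 30-gene bundle and the
200-gene standard study once per session; the acceptance script generates
the 200-gene study from its `--seed` and finishes in well under a minute
on one CPU. All randomness flows from explicit integer seeds through
NumPy generators; reports are written with sorted keys and no timestamps,
so a config + seed reproduces every output byte-for-byte.
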