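# familyscope

Genome-wide annotation of the WRKY transcription-factor family, built as a
reusable, testable pipeline. WRKY proteins are plant transcriptional
regulators defined by a ~60-residue DNA-binding domain: an N-terminal
heptapeptide (canonically `WRKYGQK`) followed by a zinc finger whose
coordinating residues follow `C-X(n1)-C-X(n2)-H-X-(H|C)`. The family splits
into Group I (two domains), Group II (one domain, C2H2 finger; subgroups
IIa–IIe) and Group III (one domain, C2HC finger). familyscope re-implements
the full annotation workflow used in comparative surveys of legume genomes —
two *Vigna* crops, Adzuki bean (84 *WRKY* genes) and Mung bean (85), are the
motivating case — for anyone who needs the same analysis on a new proteome
or wants each step as a tested library function.

What the library does:

- **Domain discovery by motif grammar** (`familyscope.domains`): exact
  heptapeptide matching over a closed variant set (`WRKYGQK`, `WRKYGKK`,
  `WRKYGEK`, `WKKYGQK`, `SRKYGQK`) plus a zinc-finger search over
  `C X{4..7} C X{21..30} H X (H|C)`, with truncation flags
  (missing heptapeptide / missing finger) and NTWD/CTWD roles.
- **Classification** (`familyscope.classify`): two domains → I; single C2HC →
  III; single C2H2 with n1 = 4 → IIc; single C2H2 with n1 ≥ 5 is resolved
  against labeled reference domains by alignment distance (IIa/IIb/IId/IIe
  share one grammar signature). Isoform collapsing (longest protein per
  locus), redundant-protein flags, the Group IId HARF motif
  `RTGHARFRR(A/G)P`, and percentage summaries.
- **Protein properties** (`familyscope.props`): average molecular weight and
  isoelectric point (bisection on the Henderson–Hasselbalch net charge).
- **Gene structure** (`familyscope.structure`): intron phases from GFF3 CDS
  segments, residue↔genome coordinate mapping, and typing of the two
  conserved domain introns — R-type (phase 2, spliced exactly after the
  conserved Arg before the finger) and V-type (phase 0, just before the Val
  six residues after the finger's second Cys).
- **Duplication** (`familyscope.genome_map`): gene clusters (≥2 family genes
  within 200 kb), tandem pairs (≤100 kb, ≤3 spacer genes) and segmental
  pairs (high-identity paralogs on different chromosomes).
- **Phylogeny** (`familyscope.phylo`): global pairwise alignment with pinned
  tie-breaks, center-star multiple alignment, p-distances, Saitou–Nei
  neighbor joining, seeded column bootstrap, nearest-labeled-reference
  queries.
- **Promoters** (`familyscope.promoters`): 1.5 kb upstream windows and
  both-strand IUPAC scans against a bundled PLACE/PlantCARE-style element
  dictionary (replaceable TSV input).
- **Expression** (`familyscope.expression`): FPKM ≥ 0.5 detection filter and
  the log2(FPKM+1) transform.
- **Synthetic genomes with truth tables** (`familyscope.synth`,
  `familyscope.plan`): a seeded generator that plants WRKY genes of every
  group (signature variants, truncations, isoforms, both strands), decoys,
  clusters/tandem/segmental islands, promoter elements and FPKM values —
  so the whole pipeline can be validated against known truth.

## Worked example

`examples/` holds one short script per capability. The round trip in
`examples/03_synthetic_bundle_pipeline.py` generates a 30-gene synthetic
genome and re-annotates it from the files alone:

```text
planted genes: 30, group labels recovered: 30
family records from decoys: 0
group counts: {'I': 2, 'IIa': 1, 'IIb': 4, 'IIc': 9, 'IId': 3, 'IIe': 6, 'III': 5}
clusters found: [['W001', 'W002'], ['W003', 'W004'], ['W005', 'W006', 'W007'], ['W008', 'W009'], ['W010', 'W011']]
tandem pairs: [('W001', 'W002', 0), ('W003', 'W004', 3), ('W010', 'W011', 1)]
expressed genes: 19 of 30
```

Every planted group label is recovered, no decoy protein enters the family,
and the five planted clusters and three tandem pairs (with 0, 3 and 1
spacer genes) come back exactly. `examples/02_family_summary.py` prints the
published count arithmetic, e.g. for Adzuki bean:

```text
Adzuki bean: 84 WRKY genes
  I     15   17.9%
  ...
  IIa+IIb combined ~ 23%
```

A thin CLI wraps the same functions
(`familyscope scan|classify|structure|promoter|expr|synth|all`), e.g.:

```bash
familyscope synth --seed 5 --n-wrky 15 --n-decoys 6 --out-dir bundle/
familyscope all --proteome bundle/proteome.fasta --genome bundle/genome.fasta \
    --gff3 bundle/genes.gff3 --references bundle/references.fasta \
    --reference-labels bundle/reference_labels.tsv --fpkm bundle/fpkm.tsv \
    --out-dir out/
```

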