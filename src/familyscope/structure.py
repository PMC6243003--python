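"""Exon-intron architecture, intron phases, and R-/V-type intron calling.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the boundary.  Intron phase is the cumulative length of the
upstream coding sequence modulo 3, counted from the ATG of the CDS in
transcription order (minus-strand exons are walked 3' to 5' genomically).

Two conserved domain introns are typed: the R-type, a phase-2 intron spliced
exactly after a conserved arginine between the heptapeptide and the zinc
finger; and the V-type, a phase-0 intron just before the valine six residues
after the second cysteine of a C2H2 finger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import gffutils
from Bio.Seq import Seq, reverse_complement

from .domains import WrkyDomain


@dataclass
class GeneModel:
    gene_id: str
    transcript_id: str
    seq_id: str
    strand: str
    cds: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open

    def __post_init__(self) -> None:
        self.cds = sorted(self.cds)
        prev_end = None
        for s, e in self.cds:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty CDS segment ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
            prev_end = e
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.cds[0][0]

    @property
    def end(self) -> int:
        return self.cds[-1][1]

    def transcription_order(self) -> list[tuple[int, int]]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def spliced_cds(self, genome: dict[str, str]) -> str:
        contig = genome[self.seq_id]
        parts = [contig[s:e] for s, e in self.cds]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)

    def translate(self, genome: dict[str, str]) -> str:
        prot = str(Seq(self.spliced_cds(genome)).translate())
        return prot[:-1] if prot.endswith("*") else prot


@dataclass(frozen=True)
class Intron:
    gene_id: str
    index: int  # 5'->3' in transcription order
    start: int  # genomic, 0-based half-open
    end: int
    phase: int
    type: str = "other"  # R | V | other
    host_codon_protein_index: Optional[int] = None


def genes_from_gff3(path_or_text: str, from_string: bool = False) -> list[GeneModel]:
    """Parse gene models (gene/mRNA/CDS) from GFF3 via an in-memory gffutils db.

    One GeneModel per mRNA; gene_id comes from the mRNA's parent gene.
    """
    db = gffutils.create_db(
        path_or_text,
        dbfn=":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        cds = [
            (c.start - 1, c.end)
            for c in db.children(mrna, featuretype="CDS", order_by="start")
        ]
        if not cds:
            continue
        models.append(GeneModel(gene_id, mrna.id, mrna.seqid, mrna.strand, cds))
    return models


def introns_of(gene: GeneModel) -> list[Intron]:
    """Introns (gaps between consecutive CDS segments) with phases."""
    if not gene.cds:
        raise ValueError(f"{gene.gene_id}: zero CDS segments")
    segs = gene.transcription_order()
    introns = []
    cum = 0
    for k in range(len(segs) - 1):
        s, e = segs[k]
        cum += e - s
        if gene.strand == "+":
            g_start, g_end = segs[k][1], segs[k + 1][0]
        else:
            g_start, g_end = segs[k + 1][1], segs[k][0]
        introns.append(Intron(gene.gene_id, k, g_start, g_end, cum % 3))
    return introns


def map_residue_to_genome(gene: GeneModel, residue_index: int) -> int:
    """Genomic coordinate (0-based) of the first base of a residue's codon."""
    total = sum(e - s for s, e in gene.cds)
    if residue_index < 0 or 3 * residue_index >= total:
        raise IndexError(
            f"{gene.gene_id}: residue {residue_index} outside spliced CDS"
        )
    offset = 3 * residue_index  # transcript coordinate of the codon start
    for s, e in gene.transcription_order():
        seg_len = e - s
        if offset < seg_len:
            return s + offset if gene.strand == "+" else e - 1 - offset
        offset -= seg_len
    raise AssertionError("unreachable")


def type_domain_introns(
    gene: GeneModel,
    domains: Sequence[WrkyDomain],
    protein: str,
    lenient_v: bool = False,
) -> list[Intron]:
    """Classify each intron of ``gene`` as R-type, V-type or other.

    R-type: phase 2, splitting a codon between the heptapeptide and the
    finger's first cysteine, with the last complete upstream codon encoding R.
    V-type: phase 0, with the next codon at protein index c2+6 of a C2H2
    finger; that residue must be V unless ``lenient_v``.
    """
    out = []
    segs = gene.transcription_order()
    cum = 0
    cums = []
    for k in range(len(segs) - 1):
        cum += segs[k][1] - segs[k][0]
        cums.append(cum)
    for intron, cum in zip(introns_of(gene), cums):
        itype = "other"
        host: Optional[int] = None
        if intron.phase == 2:
            r = cum // 3  # residue whose codon the intron interrupts
            for d in domains:
                if d.heptapeptide is None or d.zinc_finger is None:
                    continue
                hepta_end = d.heptapeptide.start + 7
                if (
                    r - 1 >= hepta_end
                    and r <= d.zinc_finger.c1
                    and r - 1 < len(protein)
                    and protein[r - 1] == "R"
                ):
                    itype, host = "R", r
                    break
        elif intron.phase == 0:
            k = cum // 3  # first residue downstream of the intron
            for d in domains:
                zf = d.zinc_finger
                if zf is None or zf.finger_class != "C2H2":
                    continue
                if k == zf.c2 + 6 and k < len(protein):
                    if lenient_v or protein[k] == "V":
                        itype, host = "V", k
                        break
        out.append(
            Intron(
                intron.gene_id, intron.index, intron.start, intron.end,
                intron.phase, itype, host,
            )
        )
    return out


def introns_to_tsv(introns: Sequence[Intron], seq_id: str = "") -> list[str]:
    return [
        f"{i.gene_id}\t{i.index}\t{i.phase}\t{i.type}\t{i.start}\t{i.end}"
        for i in introns
    ]
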