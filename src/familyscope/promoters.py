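"""Promoter extraction and IUPAC cis-element scanning.

The promoter is the 1.5 kb immediately 5' of the translation start on the
coding strand.  Hits are reported relative to the start codon: the base
immediately upstream of the A of ATG has offset -1, and every hit is
anchored at its 5'-most promoter coordinate in the plus-strand frame.
Both strands are scanned; overlapping occurrences are all reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

PROMOTER_LENGTH = 1500

_IUPAC = {k.upper(): set(v.upper()) for k, v in ambiguous_dna_values.items()}


@dataclass(frozen=True)
class MotifElement:
    name: str
    consensus: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"{self.name}: empty consensus")
        bad = set(self.consensus.upper()) - set("ACGTRYSWKMBDHVN")
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC letters {sorted(bad)}")

    def regex(self) -> re.Pattern[str]:
        parts = []
        for ch in self.consensus.upper():
            allowed = "".join(sorted(_IUPAC[ch]))
            parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
        # Lookahead so overlapping occurrences are all found.
        return re.compile("(?=(" + "".join(parts) + "))")


@dataclass(frozen=True)
class ElementHit:
    gene_id: str
    element: str
    offset: int  # 5'-most base of the hit, plus-strand frame; -1 abuts ATG
    strand: str  # "+" | "-"
    sequence: str  # matching sequence on the hit's strand


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    sequence: str  # coding-strand orientation, 5'->3', ends just before ATG
    truncated: bool = False


def load_elements(path=None) -> list[MotifElement]:
    """Read an element dictionary TSV (name, IUPAC consensus[, source]).

    Without ``path`` the bundled dictionary of published PLACE/PlantCARE
    consensi is used; it is replaceable input, not ground truth.
    """
    if path is None:
        text = (
            resources.files("familyscope.data")
            .joinpath("cis_elements.tsv")
            .read_text()
        )
        lines = text.splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    out = []
    for line in lines:
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        fields = line.rstrip("\n").split("\t")
        out.append(MotifElement(fields[0], fields[1], fields[2] if len(fields) > 2 else ""))
    return out


def extract_promoter(genome: dict[str, str], gene, length: int = PROMOTER_LENGTH) -> Promoter:
    """Upstream ``length`` bases of a gene model's translation start.

    ``gene`` needs ``seq_id``, ``strand`` and ``cds`` (list of 0-based
    half-open (start, end) genomic segments).  Minus-strand promoters are
    reverse-complemented; windows clipped at a contig edge are flagged.
    """
    if gene.seq_id not in genome:
        raise KeyError(f"sequence {gene.seq_id!r} not in genome")
    if not gene.cds:
        raise ValueError(f"{gene.gene_id}: no CDS segments")
    contig = genome[gene.seq_id]
    if gene.strand == "+":
        atg = min(s for s, _ in gene.cds)
        lo = max(0, atg - length)
        seq = contig[lo:atg]
        truncated = atg - length < 0
    else:
        atg = max(e for _, e in gene.cds)
        hi = min(len(contig), atg + length)
        seq = reverse_complement(contig[atg:hi])
        truncated = atg + length > len(contig)
    return Promoter(gene.gene_id, seq, truncated)


def scan(promoter: Promoter, elements: Sequence[MotifElement]) -> list[ElementHit]:
    """All exact IUPAC matches of every element, on both strands."""
    seq = promoter.sequence.upper()
    L = len(seq)
    rc = reverse_complement(seq)
    hits: list[ElementHit] = []
    for el in elements:
        pat = el.regex()
        for m in pat.finditer(seq):
            p = m.start()
            matched = m.group(1)
            hits.append(ElementHit(promoter.gene_id, el.name, p - L, "+", matched))
        for m in pat.finditer(rc):
            q = m.start()
            matched = m.group(1)
            p = L - q - len(matched)  # 5'-most plus-frame coordinate
            hits.append(ElementHit(promoter.gene_id, el.name, p - L, "-", matched))
    hits.sort(key=lambda h: (h.offset, h.element, h.strand))
    return hits


def hits_to_tsv(hits: Sequence[ElementHit]) -> str:
    lines = ["gene_id\telement\toffset\tstrand\tsequence"]
    for h in hits:
        lines.append(f"{h.gene_id}\t{h.element}\t{h.offset}\t{h.strand}\t{h.sequence}")
    return "\n".join(lines) + "\n"
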