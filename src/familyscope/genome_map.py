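"""Chromosomal placement, gene clusters, tandem and segmental duplications.

Definitions follow the comparative-genomics conventions used for plant TF
families: a gene cluster is a chromosomal region with two or more family
genes within 200 kb; a tandem pair sits within 100 kb on one sequence with
at most a few spacer genes in between; a segmental pair is a high-identity
paralog pair on different chromosomes (or far apart on one).  Gene-to-gene
distance is measured start-to-start, which is robust to unannotated UTRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from . import phylo

CLUSTER_WINDOW = 200_000
TANDEM_WINDOW = 100_000
MAX_SPACERS = 3
SEGMENTAL_IDENTITY_MIN = 70.0
SEGMENTAL_COVERAGE_MIN = 60.0

#: edlib normalized-distance prefilter before the exact alignment.
_PREFILTER_MAX_NORM_DIST = 0.45


@dataclass(frozen=True)
class GenomicLocus:
    gene_id: str
    seq_id: str
    start: int  # 0-based
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    @property
    def is_scaffold(self) -> bool:
        return self.seq_id.lower().startswith(("scaffold", "contig"))


@dataclass(frozen=True)
class TandemPair:
    gene_a: str
    gene_b: str
    distance: int  # start-to-start, bp
    n_spacer_genes: int


@dataclass(frozen=True)
class SegmentalPair:
    gene_a: str
    gene_b: str
    identity: float  # percent
    coverage: float  # percent


@dataclass
class DuplicationReport:
    clusters: list[list[str]] = field(default_factory=list)
    tandem_pairs: list[TandemPair] = field(default_factory=list)
    segmental_pairs: list[SegmentalPair] = field(default_factory=list)


def find_clusters(
    wrky_loci: Sequence[GenomicLocus],
    cluster_window: int = CLUSTER_WINDOW,
) -> list[list[str]]:
    """Maximal chains of family genes with consecutive start-to-start gaps
    within ``cluster_window`` on one sequence; singletons are dropped."""
    clusters: list[list[str]] = []
    by_seq: dict[str, list[GenomicLocus]] = {}
    for loc in wrky_loci:
        by_seq.setdefault(loc.seq_id, []).append(loc)
    for seq_id in sorted(by_seq):
        loci = sorted(by_seq[seq_id], key=lambda l: (l.start, l.gene_id))
        chain = [loci[0]]
        for loc in loci[1:]:
            if loc.start - chain[-1].start <= cluster_window:
                chain.append(loc)
            else:
                if len(chain) >= 2:
                    clusters.append([l.gene_id for l in chain])
                chain = [loc]
        if len(chain) >= 2:
            clusters.append([l.gene_id for l in chain])
    return clusters


def find_tandem(
    wrky_loci: Sequence[GenomicLocus],
    all_gene_loci: Sequence[GenomicLocus],
    tandem_window: int = TANDEM_WINDOW,
    max_spacers: int = MAX_SPACERS,
) -> list[TandemPair]:
    """Family-gene pairs on one sequence within ``tandem_window`` bp
    (start-to-start) separated by at most ``max_spacers`` genes.

    The spacer count is the number of annotated genes lying wholly between
    the two family genes.
    """
    pairs: list[TandemPair] = []
    by_seq: dict[str, list[GenomicLocus]] = {}
    for loc in wrky_loci:
        by_seq.setdefault(loc.seq_id, []).append(loc)
    all_by_seq: dict[str, list[GenomicLocus]] = {}
    for loc in all_gene_loci:
        all_by_seq.setdefault(loc.seq_id, []).append(loc)
    for seq_id in sorted(by_seq):
        loci = sorted(by_seq[seq_id], key=lambda l: (l.start, l.gene_id))
        others = all_by_seq.get(seq_id, [])
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                a, b = loci[i], loci[j]
                dist = b.start - a.start
                if dist > tandem_window:
                    break
                spacers = sum(
                    1
                    for g in others
                    if g.gene_id not in (a.gene_id, b.gene_id)
                    and g.start > a.end
                    and g.end < b.start
                )
                if spacers <= max_spacers:
                    pairs.append(TandemPair(a.gene_id, b.gene_id, dist, spacers))
    return pairs


def find_segmental(
    sequences: dict[str, str],
    loci: dict[str, GenomicLocus],
    identity_min: float = SEGMENTAL_IDENTITY_MIN,
    coverage_min: float = SEGMENTAL_COVERAGE_MIN,
    cluster_window: int = CLUSTER_WINDOW,
) -> list[SegmentalPair]:
    """High-identity paralog pairs on different sequences, or on one sequence
    separated by more than ``cluster_window``.

    Candidate pairs are prefiltered with a fast edit-distance bound, then
    measured with the exact global aligner (identity over alignment length,
    coverage of the longer protein).
    """
    gene_ids = sorted(set(sequences) & set(loci))
    out: list[SegmentalPair] = []
    for i in range(len(gene_ids)):
        for j in range(i + 1, len(gene_ids)):
            a, b = gene_ids[i], gene_ids[j]
            la, lb = loci[a], loci[b]
            if la.seq_id == lb.seq_id and abs(la.start - lb.start) <= cluster_window:
                continue
            sa, sb = sequences[a], sequences[b]
            if not sa or not sb:
                continue
            d = edlib.align(sa, sb, mode="NW", task="distance")["editDistance"]
            if d / max(len(sa), len(sb)) > _PREFILTER_MAX_NORM_DIST:
                continue
            aln, _ = phylo.pairwise_align(sa, sb, ids=(a, b))
            identity, coverage = phylo.identity_and_coverage(aln)
            if identity >= identity_min and coverage >= coverage_min:
                out.append(SegmentalPair(a, b, identity, coverage))
    return out


def report(
    wrky_loci: Sequence[GenomicLocus],
    all_gene_loci: Sequence[GenomicLocus],
    sequences: Optional[dict[str, str]] = None,
    cluster_window: int = CLUSTER_WINDOW,
    tandem_window: int = TANDEM_WINDOW,
    max_spacers: int = MAX_SPACERS,
    identity_min: float = SEGMENTAL_IDENTITY_MIN,
    coverage_min: float = SEGMENTAL_COVERAGE_MIN,
) -> DuplicationReport:
    rep = DuplicationReport(
        clusters=find_clusters(wrky_loci, cluster_window),
        tandem_pairs=find_tandem(wrky_loci, all_gene_loci, tandem_window, max_spacers),
    )
    if sequences:
        locmap = {l.gene_id: l for l in wrky_loci}
        rep.segmental_pairs = find_segmental(
            sequences, locmap, identity_min, coverage_min, cluster_window
        )
    return rep


def clusters_to_bed(
    clusters: Sequence[Sequence[str]], loci: dict[str, GenomicLocus]
) -> str:
    """BED lines (0-based half-open) spanning each cluster."""
    lines = []
    for k, genes in enumerate(clusters):
        members = [loci[g] for g in genes]
        seq_id = members[0].seq_id
        start = min(m.start for m in members)
        end = max(m.end for m in members)
        lines.append(f"{seq_id}\t{start}\t{end}\tcluster_{k + 1}")
    return "\n".join(lines) + ("\n" if lines else "")
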