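"""Seeded synthetic genomes with a known truth table.

The generator emulates every structure the annotation pipeline assumes:
proteomes containing WRKY proteins of every group with the observed
heptapeptide variants and zinc-finger spacings (plus non-WRKY decoys), gene
models with R-/V-type introns at their conserved positions, chromosomes with
planted gene clusters, tandem pairs and segmental duplicates, promoters with
planted IUPAC elements, and FPKM tables straddling the detection threshold.

Design notes on exactness (the truth table must be literally true):

* Protein filler residues are drawn from an alphabet without C, H and Y.
  Every accepted heptapeptide variant contains Y and every zinc finger needs
  C and H, so spurious domains cannot arise in filler; planted motifs are the
  only matches.  Decoy filler omits H and Y, so decoys can contain cysteines
  yet never a finger or heptapeptide.
* Within a subgroup, domain sequences share a per-spec prototype (plus at
  most two point substitutions per gene) and carry a 6-residue subgroup
  marker in the zinc-finger spacer, so nearest-reference classification of
  the grammar-ambiguous subgroups is unambiguous by construction.
* Promoter windows are random sequence repaired until the bundled element
  dictionary matches exactly the planted occurrences on both strands.
* Genes outside declared islands are spaced farther apart than the cluster
  window, so cluster/tandem truth is what the plan declares.

The generator does not simulate reads, codon bias or indel/SNP noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import reverse_complement

from . import promoters as promoter_mod
from .promoters import MotifElement, Promoter, load_elements

#: Protein filler: no C/H (would seed zinc fingers) and no Y (in every
#: heptapeptide variant).
FILLER_AA = "ADEFGIKLMNPQRSTVW"
#: Decoy filler: cysteines allowed, but no H (fingers) and no Y (heptapeptides).
DECOY_AA = "ACDEFGIKLMNPQRSTVW"

PROMOTER_LEN = 1500
DEFAULT_INTRON_LEN = 150

_CODONS: dict[str, list[str]] = {}
for codon, aa in unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

SUBGROUP_MARKERS = {
    "IIa": "AQAQAQ",
    "IIb": "DEDEDE",
    "IIc": "PSPSPS",
    "IId": "KGKGKG",
    "IIe": "NTNTNT",
    "III": "LVLVLV",
    "I-NTWD": "FMFMFM",
    "I-CTWD": "ISISIS",
}


@dataclass
class DomainPlan:
    """One planted WRKY domain."""

    subgroup_key: str  # prototype key, e.g. "IIc", "I-NTWD"
    heptapeptide: Optional[str] = "WRKYGQK"  # None -> finger-only truncation
    n1: int = 4
    n2: int = 23
    terminal: str = "H"  # H -> C2H2, C -> C2HC

    @property
    def signature(self) -> str:
        return f"CX{self.n1}CX{self.n2}HX{self.terminal}"


@dataclass
class IntronPlan:
    kind: str  # "R" | "V" | "other"
    domain_index: int = 0  # for R/V: which planted domain hosts it
    phase: int = 0  # for "other"
    tail_residue: int = 5  # for "other": residues into the tail


@dataclass
class PlantedGene:
    gene_id: str
    group: str
    domains: list[DomainPlan]
    introns: list[IntronPlan] = field(default_factory=list)
    seq_id: str = "chr1"
    start: int = 10_000  # genomic start of the CDS span (0-based)
    strand: str = "+"
    promoter_elements: list[tuple[str, int, str]] = field(default_factory=list)
    fpkm: list[float] = field(default_factory=lambda: [1.0, 0.0, 0.0, 0.0])
    n_isoforms: int = 1
    copy_of: Optional[str] = None  # reuse another gene's protein (segmental)
    harf: bool = False
    leader_len: int = 22
    tail_len: int = 45


@dataclass
class DecoyGene:
    gene_id: str
    seq_id: str
    start: int
    strand: str = "+"
    length_aa: int = 120
    n_exons: int = 2
    fpkm: list[float] = field(default_factory=lambda: [2.0, 1.0, 0.0, 0.0])


@dataclass
class SyntheticSpec:
    seed: int
    chromosomes: dict[str, int]
    genes: list[PlantedGene]
    decoys: list[DecoyGene]
    samples: list[str] = field(default_factory=lambda: ["S1", "S2", "S3", "S4"])
    clusters: list[list[str]] = field(default_factory=list)
    tandem_pairs: list[tuple[str, str, int, int]] = field(default_factory=list)
    segmental_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Bundle:
    spec: SyntheticSpec
    out_dir: Path
    genome_path: Path
    proteome_path: Path
    gff3_path: Path
    elements_path: Path
    fpkm_path: Path
    truth_path: Path
    references_path: Path
    reference_labels_path: Path
    truth: pd.DataFrame
    genome: dict[str, str]
    proteome: dict[str, str]
    references: list[tuple[str, str, str]]


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Protein construction


def _filler(rng: np.random.Generator, n: int, alphabet: str = FILLER_AA) -> str:
    letters = np.array(list(alphabet))
    return "".join(rng.choice(letters, size=n)) if n else ""


def _assemble_domain(parts: dict, plan: DomainPlan) -> tuple[str, dict]:
    """Domain region for a (subgroup, signature) combination.

    Layout: heptapeptide, a 10-residue bridge whose 8th residue is the
    conserved R, then C, n1 spacer, C, n2 spacer (with V at c2+6 and the
    subgroup marker at c2+8..c2+13), H, one residue, terminal H/C.
    Spacers are slices of the subgroup's fixed maximum-length filler, so
    signature variants of one subgroup differ from its canonical domain by
    indels only — nearest-reference classification stays unambiguous.
    Offsets in the returned meta are relative to the domain start.
    """
    chunks: list[str] = []
    pos = 0
    meta: dict = {}
    if plan.heptapeptide is not None:
        chunks.append(plan.heptapeptide)
        meta["hepta"] = 0
        pos = 7
        meta["r_anchor"] = pos + 7
        chunks.append(parts["bridge"])
        pos += 10
    meta["c1"] = pos
    chunks.append("C")
    pos += 1
    chunks.append(parts["spacer1"][: plan.n1])
    pos += plan.n1
    meta["c2"] = pos
    chunks.append("C")
    pos += 1
    chunks.append(parts["spacer2"][: plan.n2])
    meta["v"] = meta["c2"] + 6
    pos += plan.n2
    meta["h1"] = pos
    chunks.append("H")
    chunks.append(parts["mid"])
    chunks.append(plan.terminal)
    meta["terminal"] = pos + 2
    seq = "".join(chunks)
    meta["length"] = len(seq)
    # Positions free to mutate: bridge/spacer filler, never anchors or marker.
    marker = SUBGROUP_MARKERS[plan.subgroup_key]
    fixed = {meta["c1"], meta["c2"], meta["h1"], meta["terminal"], meta["v"]}
    if plan.heptapeptide is not None:
        fixed |= set(range(0, 7)) | {meta["r_anchor"]}
    fixed |= set(range(meta["c2"] + 8, meta["c2"] + 8 + len(marker)))
    meta["mutable"] = sorted(set(range(len(seq))) - fixed - {len(seq) - 2})
    return seq, meta


class _PrototypeBank:
    """Per-subgroup domain fillers, generated once per spec.

    Spacer fillers are drawn at the grammar's maximum lengths (7 and 30) and
    sliced per signature, so e.g. a CX5CX30HXH outlier shares every aligned
    residue with its subgroup's canonical CX5CX23HXH domain.
    """

    def __init__(self, rng: np.random.Generator) -> None:
        self._rng = rng
        self._parts: dict[str, dict] = {}
        self._bank: dict[tuple, tuple[str, dict]] = {}

    def _parts_for(self, subgroup_key: str) -> dict:
        if subgroup_key not in self._parts:
            bridge = list(_filler(self._rng, 10))
            bridge[7] = "R"
            spacer2 = list(_filler(self._rng, 30))
            spacer2[5] = "V"  # residue c2+6
            marker = SUBGROUP_MARKERS[subgroup_key]
            spacer2[7 : 7 + len(marker)] = list(marker)
            self._parts[subgroup_key] = {
                "bridge": "".join(bridge),
                "spacer1": _filler(self._rng, 7),
                "spacer2": "".join(spacer2),
                "mid": _filler(self._rng, 1),
            }
        return self._parts[subgroup_key]

    def get(self, plan: DomainPlan) -> tuple[str, dict]:
        key = (plan.subgroup_key, plan.heptapeptide, plan.n1, plan.n2, plan.terminal)
        if key not in self._bank:
            self._bank[key] = _assemble_domain(self._parts_for(plan.subgroup_key), plan)
        return self._bank[key]


def _build_protein(
    rng: np.random.Generator, gene: PlantedGene, bank: _PrototypeBank
) -> tuple[str, list[dict]]:
    """Full protein sequence plus per-domain meta with absolute offsets."""
    leader = "M" + _filler(rng, gene.leader_len - 1)
    seq_parts = [leader]
    pos = len(leader)
    metas: list[dict] = []
    for i, dplan in enumerate(gene.domains):
        if i > 0:
            linker = _filler(rng, 15)
            seq_parts.append(linker)
            pos += len(linker)
        proto, meta = bank.get(dplan)
        dom = list(proto)
        if meta["mutable"]:
            n_mut = min(2, len(meta["mutable"]))
            sites = rng.choice(meta["mutable"], size=n_mut, replace=False)
            for s in sites:
                dom[int(s)] = _filler(rng, 1)
        dom_seq = "".join(dom)
        abs_meta = {
            k: (v + pos if isinstance(v, int) and k not in ("length",) else v)
            for k, v in meta.items()
            if k not in ("mutable",)
        }
        abs_meta["start"] = pos
        abs_meta["signature"] = dplan.signature
        abs_meta["heptapeptide"] = dplan.heptapeptide
        metas.append(abs_meta)
        seq_parts.append(dom_seq)
        pos += len(dom_seq)
    tail = list(_filler(rng, gene.tail_len))
    if gene.harf:
        motif = "RTGHARFRR" + str(rng.choice(["A", "G"])) + "P"
        at = 5
        tail[at : at + len(motif)] = list(motif)
    seq_parts.append("".join(tail))
    return "".join(seq_parts), metas


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(str(rng.choice(_CODONS[aa])) for aa in protein)


# ---------------------------------------------------------------------------
# Promoter construction


def _realize(rng: np.random.Generator, consensus: str) -> str:
    from Bio.Data.IUPACData import ambiguous_dna_values

    return "".join(
        str(rng.choice(sorted(ambiguous_dna_values[ch.upper()])))
        for ch in consensus
    )


def _build_promoter(
    rng: np.random.Generator,
    gene: PlantedGene,
    elements: Sequence[MotifElement],
    length: int = PROMOTER_LEN,
) -> str:
    """Random promoter window carrying exactly the planted element hits."""
    by_name = {e.name: e for e in elements}
    for name, offset, strand in gene.promoter_elements:
        el = by_name.get(name)
        if el is None:
            raise SpecError(f"{gene.gene_id}: unknown element {name}")
        if offset < -length or offset > -len(el.consensus):
            raise SpecError(
                f"{gene.gene_id}: element {name} offset {offset} outside promoter"
            )
    seq = list(_filler_dna(rng, length))
    footprints: list[tuple[int, int, str, str]] = []  # start, end, name, strand
    for name, offset, strand in gene.promoter_elements:
        el = by_name[name]
        w = len(el.consensus)
        p = offset + length
        concrete = _realize(rng, el.consensus)
        planted = concrete if strand == "+" else reverse_complement(concrete)
        for q0, q1, other, _ in footprints:
            if p < q1 and p + w > q0:
                raise SpecError(
                    f"{gene.gene_id}: elements {name} and {other} overlap"
                )
        seq[p : p + w] = list(planted)
        footprints.append((p, p + w, name, strand))

    expected = {
        (name, offset, strand) for name, offset, strand in gene.promoter_elements
    }
    for attempt in range(200):
        hits = promoter_mod.scan(
            Promoter(gene.gene_id, "".join(seq)), list(elements)
        )
        got = {(h.element, h.offset, h.strand) for h in hits}
        if got == expected:
            return "".join(seq)
        missing = expected - got
        if missing:
            raise SpecError(f"{gene.gene_id}: planted hits vanished: {missing}")
        extras = [h for h in hits if (h.element, h.offset, h.strand) not in expected]
        for h in extras[:1]:
            if not _break_hit(rng, seq, h, by_name, footprints, length):
                # Re-realize degenerate positions of overlapping planted
                # elements and retry from scratch on the filler.
                for q0, q1, name, strand in footprints:
                    el = by_name[name]
                    concrete = _realize(rng, el.consensus)
                    planted = (
                        concrete if strand == "+" else reverse_complement(concrete)
                    )
                    seq[q0:q1] = list(planted)
    raise SpecError(f"{gene.gene_id}: could not build a clean promoter")


def _break_hit(rng, seq, hit, by_name, footprints, length) -> bool:
    el = by_name[hit.element]
    w = len(el.consensus)
    p = hit.offset + length
    pat = el.regex()
    order = list(range(p, p + w))
    rng.shuffle(order)
    for pos in order:
        covered = [
            (q0, q1, name, strand)
            for q0, q1, name, strand in footprints
            if q0 <= pos < q1
        ]
        for base in "ACGT":
            if base == seq[pos]:
                continue
            old = seq[pos]
            seq[pos] = base
            window = "".join(seq[p : p + w])
            still = bool(
                pat.match(window)
                if hit.strand == "+"
                else pat.match(reverse_complement(window))
            )
            ok_planted = True
            for q0, q1, name, strand in covered:
                pel = by_name[name]
                sub = "".join(seq[q0:q1])
                if strand == "-":
                    sub = reverse_complement(sub)
                if not pel.regex().match(sub):
                    ok_planted = False
                    break
            if not still and ok_planted:
                return True
            seq[pos] = old
    return False


def _filler_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=n)) if n else ""


# ---------------------------------------------------------------------------
# Gene assembly


@dataclass
class _BuiltGene:
    gene_id: str
    seq_id: str
    strand: str
    body: str  # genomic-forward sequence of the CDS span (exons + introns)
    start: int
    promoter: Optional[str]  # coding orientation, or None
    mrnas: list[tuple[str, list[tuple[int, int]]]]  # (mRNA id, genomic CDS segs)
    proteins: dict[str, str]
    intron_types: list[str]


def _cum_positions(gene: PlantedGene, metas: list[dict], protein_len: int) -> list[tuple[int, str]]:
    """Intron insertion points as (cds_offset, kind) in transcript order."""
    points: list[tuple[int, str]] = []
    for ip in gene.introns:
        if ip.kind == "R":
            meta = metas[ip.domain_index]
            if meta.get("r_anchor") is None:
                raise SpecError(f"{gene.gene_id}: R intron needs a heptapeptide")
            cum = 3 * (meta["r_anchor"] + 1) + 2
        elif ip.kind == "V":
            meta = metas[ip.domain_index]
            cum = 3 * (meta["c2"] + 6)
        else:
            cum = 3 * (protein_len - 1 - max(1, ip.tail_residue)) + ip.phase
        if not 0 < cum < 3 * protein_len:
            raise SpecError(f"{gene.gene_id}: intron point {cum} outside CDS")
        points.append((cum, ip.kind))
    points.sort()
    if len({c for c, _ in points}) != len(points):
        raise SpecError(f"{gene.gene_id}: coincident intron points")
    return points


def _build_gene(
    rng: np.random.Generator,
    gene: PlantedGene,
    bank: _PrototypeBank,
    elements: Sequence[MotifElement],
    protein_cache: dict[str, tuple[str, list[dict]]],
) -> _BuiltGene:
    if gene.copy_of is not None:
        protein, metas = protein_cache[gene.copy_of]
    else:
        protein, metas = _build_protein(rng, gene, bank)
    protein_cache[gene.gene_id] = (protein, metas)

    cds = _back_translate(rng, protein) + "TAA"
    points = _cum_positions(gene, metas, len(protein))

    # Split the CDS at the intron points; record exon lengths.
    exon_lens: list[int] = []
    prev = 0
    for cum, _ in points:
        exon_lens.append(cum - prev)
        prev = cum
    exon_lens.append(len(cds) - prev)

    intron_seqs = [
        "GT" + _filler_dna(rng, int(rng.integers(76, 196))) + "AG"
        for _ in points
    ]

    # Transcript-forward body and transcript-relative exon coordinates.
    body_parts: list[str] = []
    t_exons: list[tuple[int, int]] = []
    tpos = 0
    ci = 0
    for k, el in enumerate(exon_lens):
        body_parts.append(cds[ci : ci + el])
        t_exons.append((tpos, tpos + el))
        tpos += el
        ci += el
        if k < len(intron_seqs):
            body_parts.append(intron_seqs[k])
            tpos += len(intron_seqs[k])
    body_fwd = "".join(body_parts)

    # Isoforms: .1 is the full model; .k (k>1) truncates k*4 residues plus the
    # stop codon off the last exon.
    mrna_exon_sets: list[list[tuple[int, int]]] = [list(t_exons)]
    for iso in range(2, gene.n_isoforms + 1):
        cut = 3 * (4 * (iso - 1)) + 3
        last = t_exons[-1]
        if last[1] - last[0] <= cut + 3:
            raise SpecError(f"{gene.gene_id}: last exon too short for isoforms")
        segs = list(t_exons[:-1]) + [(last[0], last[1] - cut)]
        mrna_exon_sets.append(segs)

    # Genomic placement.
    L = len(body_fwd)
    if gene.strand == "+":
        body = body_fwd
        to_genomic = lambda s, e: (gene.start + s, gene.start + e)
    else:
        body = reverse_complement(body_fwd)
        to_genomic = lambda s, e: (gene.start + L - e, gene.start + L - s)

    mrnas = []
    proteins = {}
    for iso, segs in enumerate(mrna_exon_sets, start=1):
        mrna_id = f"{gene.gene_id}.{iso}"
        g_segs = sorted(to_genomic(s, e) for s, e in segs)
        mrnas.append((mrna_id, g_segs))
        n_res = (sum(e - s for s, e in segs) - (3 if iso == 1 else 0)) // 3
        proteins[mrna_id] = protein[:n_res]

    promoter = _build_promoter(rng, gene, elements) if gene.strand else None
    return _BuiltGene(
        gene.gene_id,
        gene.seq_id,
        gene.strand,
        body,
        gene.start,
        promoter,
        mrnas,
        proteins,
        [kind for _, kind in points],
    )


def _build_decoy(rng: np.random.Generator, decoy: DecoyGene) -> _BuiltGene:
    protein = "M" + _filler(rng, decoy.length_aa - 1, DECOY_AA)
    cds = _back_translate(rng, protein) + "TAA"
    n_ex = max(1, decoy.n_exons)
    cut_candidates = sorted(
        int(c) for c in rng.choice(np.arange(3, len(cds) - 3), size=n_ex - 1, replace=False)
    ) if n_ex > 1 else []
    exon_lens = []
    prev = 0
    for c in cut_candidates:
        exon_lens.append(c - prev)
        prev = c
    exon_lens.append(len(cds) - prev)
    body_parts = []
    t_exons = []
    tpos = 0
    ci = 0
    for k, el in enumerate(exon_lens):
        body_parts.append(cds[ci : ci + el])
        t_exons.append((tpos, tpos + el))
        tpos += el
        ci += el
        if k < len(exon_lens) - 1:
            intron = "GT" + _filler_dna(rng, 96) + "AG"
            body_parts.append(intron)
            tpos += len(intron)
    body_fwd = "".join(body_parts)
    L = len(body_fwd)
    if decoy.strand == "+":
        body = body_fwd
        g_segs = sorted((decoy.start + s, decoy.start + e) for s, e in t_exons)
    else:
        body = reverse_complement(body_fwd)
        g_segs = sorted(
            (decoy.start + L - e, decoy.start + L - s) for s, e in t_exons
        )
    mrna_id = f"{decoy.gene_id}.1"
    return _BuiltGene(
        decoy.gene_id, decoy.seq_id, decoy.strand, body, decoy.start,
        None, [(mrna_id, g_segs)], {mrna_id: protein}, [],
    )


# ---------------------------------------------------------------------------
# Bundle assembly and serialization


def _wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def _gff3_lines(built: _BuiltGene) -> list[str]:
    lines = []
    g_start = min(s for _, segs in built.mrnas for s, _ in segs)
    g_end = max(e for _, segs in built.mrnas for _, e in segs)
    lines.append(
        f"{built.seq_id}\tfamilyscope_synth\tgene\t{g_start + 1}\t{g_end}\t.\t"
        f"{built.strand}\t.\tID={built.gene_id}"
    )
    for mrna_id, segs in built.mrnas:
        m_start = min(s for s, _ in segs)
        m_end = max(e for _, e in segs)
        lines.append(
            f"{built.seq_id}\tfamilyscope_synth\tmRNA\t{m_start + 1}\t{m_end}\t.\t"
            f"{built.strand}\t.\tID={mrna_id};Parent={built.gene_id}"
        )
        order = segs if built.strand == "+" else list(reversed(segs))
        cum = 0
        phased = []
        for s, e in order:
            phase = (3 - (cum % 3)) % 3
            phased.append((s, e, phase))
            cum += e - s
        for s, e, phase in sorted(phased):
            lines.append(
                f"{built.seq_id}\tfamilyscope_synth\tCDS\t{s + 1}\t{e}\t.\t"
                f"{built.strand}\t{phase}\tID=cds-{mrna_id};Parent={mrna_id}"
            )
    return lines


def generate(spec: SyntheticSpec, out_dir) -> Bundle:
    """Materialize a spec into FASTA/GFF3/TSV files plus the truth table.

    The same spec and seed always produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    elements = load_elements()
    bank = _PrototypeBank(rng)
    protein_cache: dict[str, tuple[str, list[dict]]] = {}

    built_genes: list[_BuiltGene] = []
    for gene in spec.genes:
        built_genes.append(_build_gene(rng, gene, bank, elements, protein_cache))
    built_decoys: list[_BuiltGene] = [
        _build_decoy(rng, d) for d in spec.decoys
    ]

    # Chromosome assembly with overlap checking.
    chrom = {name: bytearray(b"A" * length) for name, length in spec.chromosomes.items()}
    reserved: dict[str, list[tuple[int, int, str]]] = {n: [] for n in chrom}

    def paste(seq_id: str, start: int, segment: str, owner: str) -> None:
        if seq_id not in chrom:
            raise SpecError(f"{owner}: unknown chromosome {seq_id}")
        end = start + len(segment)
        if start < 0 or end > len(chrom[seq_id]):
            raise SpecError(f"{owner}: segment outside {seq_id}")
        for s, e, other in reserved[seq_id]:
            if start < e and end > s:
                raise SpecError(f"{owner}: overlaps {other} on {seq_id}")
        chrom[seq_id][start:end] = segment.encode()
        reserved[seq_id].append((start, end, owner))

    for b in built_genes + built_decoys:
        paste(b.seq_id, b.start, b.body, b.gene_id)
        if b.promoter is not None:
            if b.strand == "+":
                paste(b.seq_id, b.start - len(b.promoter), b.promoter, b.gene_id + ":promoter")
            else:
                paste(
                    b.seq_id,
                    b.start + len(b.body),
                    reverse_complement(b.promoter),
                    b.gene_id + ":promoter",
                )

    genome = {name: bytes(buf).decode() for name, buf in chrom.items()}

    # Proteome.
    proteome: dict[str, str] = {}
    for b in built_genes + built_decoys:
        for mrna_id, _ in b.mrnas:
            proteome[mrna_id] = b.proteins[mrna_id]

    # References: subgroup prototypes for the classifier.
    references: list[tuple[str, str, str]] = []
    for key in ("IIa", "IIb", "IIc", "IId", "IIe", "III"):
        plan = DomainPlan(
            key,
            "WRKYGQK",
            7 if key == "III" else (4 if key == "IIc" else 5),
            23,
            "C" if key == "III" else "H",
        )
        proto, _ = bank.get(plan)
        references.append((f"REF_{key}", key, proto))

    # Truth table.
    by_id = {g.gene_id: g for g in spec.genes}
    tandem_partners: dict[str, list[str]] = {}
    for a, bgid, _, _ in spec.tandem_pairs:
        tandem_partners.setdefault(a, []).append(bgid)
        tandem_partners.setdefault(bgid, []).append(a)
    cluster_of: dict[str, int] = {}
    for k, members in enumerate(spec.clusters):
        for gid in members:
            cluster_of[gid] = k + 1
    segmental_of: dict[str, str] = {}
    for a, bgid in spec.segmental_pairs:
        segmental_of[a] = bgid
        segmental_of[bgid] = a

    rows = []
    for g, b in zip(spec.genes, built_genes):
        protein, metas = protein_cache[g.gene_id]
        heptas = "/".join(m["heptapeptide"] or "-" for m in metas)
        sigs = "/".join(m["signature"] for m in metas)
        fmax = max(g.fpkm)
        status = (
            "expressed" if fmax >= 0.5 else
            ("not_detected" if fmax == 0.0 else "below_threshold")
        )
        rows.append(
            {
                "gene_id": g.gene_id,
                "group": g.group,
                "heptapeptides": heptas,
                "signatures": sigs,
                "n_domains": len(metas),
                "intron_types": ",".join(b.intron_types) if b.intron_types else "-",
                "seq_id": g.seq_id,
                "start": g.start,
                "strand": g.strand,
                "cluster": cluster_of.get(g.gene_id, 0),
                "tandem_partners": ",".join(sorted(tandem_partners.get(g.gene_id, []))) or "-",
                "segmental_partner": segmental_of.get(g.gene_id, "-"),
                "element_hits": ";".join(
                    f"{n}:{o}:{s}" for n, o, s in sorted(g.promoter_elements, key=lambda t: t[1])
                ) or "-",
                "expression_status": status,
                "n_isoforms": g.n_isoforms,
                "harf": int(g.harf),
            }
        )
    truth = pd.DataFrame(rows)

    # FPKM matrix (planted genes and decoys).
    fpkm_rows = {g.gene_id: g.fpkm for g in spec.genes}
    fpkm_rows.update({d.gene_id: d.fpkm for d in spec.decoys})
    fpkm = pd.DataFrame.from_dict(fpkm_rows, orient="index", columns=spec.samples)
    fpkm.index.name = "gene_id"

    # Serialize.
    genome_path = out / "genome.fasta"
    with open(genome_path, "w") as fh:
        for name in spec.chromosomes:
            fh.write(f">{name}\n{_wrap_fasta(genome[name])}\n")
    proteome_path = out / "proteome.fasta"
    with open(proteome_path, "w") as fh:
        for pid in proteome:
            fh.write(f">{pid}\n{_wrap_fasta(proteome[pid])}\n")
    gff3_path = out / "genes.gff3"
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for b in built_genes + built_decoys:
            fh.write("\n".join(_gff3_lines(b)) + "\n")
    elements_path = out / "cis_elements.tsv"
    with open(elements_path, "w") as fh:
        fh.write("name\tconsensus\tsource\n")
        for el in elements:
            fh.write(f"{el.name}\t{el.consensus}\t{el.source}\n")
    fpkm_path = out / "fpkm.tsv"
    fpkm.to_csv(fpkm_path, sep="\t")
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    references_path = out / "references.fasta"
    with open(references_path, "w") as fh:
        for rid, _, seq in references:
            fh.write(f">{rid}\n{_wrap_fasta(seq)}\n")
    reference_labels_path = out / "reference_labels.tsv"
    with open(reference_labels_path, "w") as fh:
        fh.write("ref_id\tgroup\n")
        for rid, label, _ in references:
            fh.write(f"{rid}\t{label}\n")
    with open(out / "spec.json", "w") as fh:
        json.dump(
            {
                "seed": spec.seed,
                "chromosomes": spec.chromosomes,
                "n_genes": len(spec.genes),
                "n_decoys": len(spec.decoys),
            },
            fh,
            indent=2,
            sort_keys=True,
        )

    return Bundle(
        spec, out, genome_path, proteome_path, gff3_path, elements_path,
        fpkm_path, truth_path, references_path, reference_labels_path,
        truth, genome, proteome, references,
    )
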