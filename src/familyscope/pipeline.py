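"""End-to-end orchestration of the annotation stages.

``run_all`` reads a proteome, gene models, genome, labeled reference
domains, a cis-element dictionary and an FPKM table, runs every stage whose
inputs are present, and writes deterministic machine-readable reports.
Protein ids are mRNA ids; the gene id is the mRNA id with its trailing
isoform suffix stripped.  Stages never mutate each other's inputs, and the
same config and seed reproduce the reports byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from . import __version__, classify, expression, genome_map, phylo, promoters, structure
from .domains import (
    FINGER_WINDOW,
    HEPTAPEPTIDE_LOOKBACK,
    HEPTAPEPTIDE_VARIANTS,
    scan_protein,
)


@dataclass
class PipelineConfig:
    proteome: Optional[str] = None
    genome: Optional[str] = None
    gff3: Optional[str] = None
    references: Optional[str] = None  # FASTA of labeled reference domains
    reference_labels: Optional[str] = None  # TSV ref_id -> group
    elements: Optional[str] = None  # None -> bundled dictionary
    fpkm: Optional[str] = None
    out_dir: str = "familyscope_out"
    seed: int = 0
    heptapeptide_variants: tuple[str, ...] = HEPTAPEPTIDE_VARIANTS
    finger_window: int = FINGER_WINDOW
    heptapeptide_lookback: int = HEPTAPEPTIDE_LOOKBACK
    cluster_window: int = genome_map.CLUSTER_WINDOW
    tandem_window: int = genome_map.TANDEM_WINDOW
    max_spacers: int = genome_map.MAX_SPACERS
    segmental_identity_min: float = genome_map.SEGMENTAL_IDENTITY_MIN
    segmental_coverage_min: float = genome_map.SEGMENTAL_COVERAGE_MIN
    promoter_length: int = promoters.PROMOTER_LENGTH
    fpkm_threshold: float = expression.FPKM_THRESHOLD
    bootstrap_replicates: int = 0  # supports are opt-in at pipeline level
    lenient_v: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        if "heptapeptide_variants" in data:
            data["heptapeptide_variants"] = tuple(data["heptapeptide_variants"])
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (where the reports
        are written does not change what they contain)."""
        data = dataclasses.asdict(self)
        data.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    records: list[classify.FamilyRecord] = field(default_factory=list)
    gene_records: list[classify.FamilyRecord] = field(default_factory=list)
    summary: Optional[classify.FamilySummary] = None
    introns: dict[str, list[structure.Intron]] = field(default_factory=dict)
    duplication: Optional[genome_map.DuplicationReport] = None
    tree_newick: Optional[str] = None
    element_hits: dict[str, list[promoters.ElementHit]] = field(default_factory=dict)
    expression_call: Optional[expression.ExpressionCall] = None
    skipped: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def _read_references(fasta_path: str, labels_path: str) -> list[tuple[str, str, str]]:
    seqs = _read_fasta(fasta_path)
    refs = []
    with open(labels_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("ref_id"):
                continue
            rid, label = line.split("\t")[:2]
            refs.append((rid, label.strip(), seqs[rid]))
    return refs


def run_all(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    result.provenance = {
        "tool": "familyscope",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    if config.proteome is None:
        raise ValueError("a proteome FASTA is required")
    proteome = _read_fasta(config.proteome)

    # --- domain scan + classification ------------------------------------
    references: list[tuple[str, str, str]] = []
    if config.references and config.reference_labels:
        references = _read_references(config.references, config.reference_labels)
    for pid in sorted(proteome):
        seq = proteome[pid]
        domains = scan_protein(
            pid, seq, config.heptapeptide_variants,
            config.finger_window, config.heptapeptide_lookback,
        )
        if not domains:
            continue
        rec = classify.FamilyRecord(pid, classify.gene_id_of(pid), seq, domains)
        classify.assign_group(rec, references)
        result.records.append(rec)
    result.gene_records = classify.collapse_isoforms(result.records)
    try:
        result.summary = classify.summarize(
            [r for r in result.gene_records if r.group in classify.GROUPS]
        )
    except ValueError:
        result.summary = None

    family_gene_ids = {r.gene_id for r in result.gene_records}
    rep_by_gene = {r.gene_id: r for r in result.gene_records}

    # --- gene models -------------------------------------------------------
    models: dict[str, structure.GeneModel] = {}
    if config.gff3:
        for model in structure.genes_from_gff3(config.gff3):
            models[model.transcript_id] = model
    else:
        result.skipped.append("gene_structure (no GFF3)")
        result.skipped.append("genome_map (no GFF3)")
        result.skipped.append("promoter_scan (no GFF3)")

    if models:
        mismatches = [
            r.protein_id for r in result.records if r.protein_id not in models
        ]
        if mismatches:
            raise ValueError(
                "protein ids missing from GFF3 mRNAs: " + ", ".join(sorted(mismatches)[:20])
            )
        for gene_id in sorted(family_gene_ids):
            rec = rep_by_gene[gene_id]
            model = models[rec.protein_id]
            result.introns[gene_id] = structure.type_domain_introns(
                model, rec.domains, rec.sequence, config.lenient_v
            )

        # --- duplication -------------------------------------------------
        gene_models: dict[str, structure.GeneModel] = {}
        for m in models.values():
            cur = gene_models.get(m.gene_id)
            if cur is None or (m.end - m.start) > (cur.end - cur.start):
                gene_models[m.gene_id] = m
        all_loci = [
            genome_map.GenomicLocus(g, m.seq_id, m.start, m.end, m.strand)
            for g, m in sorted(gene_models.items())
        ]
        wrky_loci = [l for l in all_loci if l.gene_id in family_gene_ids]
        sequences = {r.gene_id: r.sequence for r in result.gene_records}
        result.duplication = genome_map.report(
            wrky_loci, all_loci, sequences,
            config.cluster_window, config.tandem_window, config.max_spacers,
            config.segmental_identity_min, config.segmental_coverage_min,
        )

    # --- phylogeny ---------------------------------------------------------
    domain_seqs: list[tuple[str, str]] = []
    for rec in result.gene_records:
        d = rec.domains[0]
        domain_seqs.append(
            (rec.gene_id, rec.sequence[d.domain_start : d.domain_end + 1])
        )
    for rid, label, seq in references:
        domain_seqs.append((f"{rid}|{label}", seq))
    if len(domain_seqs) >= 3:
        aln = phylo.progressive_align(
            [s for _, s in domain_seqs], [n for n, _ in domain_seqs]
        )
        if config.bootstrap_replicates > 0 and len(domain_seqs) >= 4:
            tree = phylo.bootstrap(
                aln, config.bootstrap_replicates, seed=config.seed
            )
        else:
            tree = phylo.neighbor_joining(phylo.p_distance(aln, on_undefined="max"))
        result.tree_newick = tree.newick()
    else:
        result.skipped.append("phylogeny (fewer than three domains)")

    # --- promoters ----------------------------------------------------------
    if models and config.genome:
        genome = _read_fasta(config.genome)
        elements = promoters.load_elements(config.elements)
        for gene_id in sorted(family_gene_ids):
            model = models[rep_by_gene[gene_id].protein_id]
            prom = promoters.extract_promoter(genome, model, config.promoter_length)
            prom = promoters.Promoter(gene_id, prom.sequence, prom.truncated)
            result.element_hits[gene_id] = promoters.scan(prom, elements)
    elif models:
        result.skipped.append("promoter_scan (no genome)")

    # --- expression ----------------------------------------------------------
    if config.fpkm:
        m = expression.read_fpkm(config.fpkm)
        fam = m.loc[[g for g in m.index if g in family_gene_ids]]
        result.expression_call = expression.expressed_genes(fam, config.fpkm_threshold)
    else:
        result.skipped.append("expression (no FPKM matrix)")

    _write_reports(config, result, out)
    return result


def _write_reports(config: PipelineConfig, result: PipelineResult, out: Path) -> None:
    (out / "family_table.tsv").write_text(classify.records_to_tsv(result.gene_records))
    report: dict = {"provenance": result.provenance, "skipped": sorted(result.skipped)}
    if result.summary:
        report["summary"] = {
            "counts": result.summary.counts,
            "percentages": result.summary.percentages,
            "combined_IIa_IIb": result.summary.combined_IIa_IIb,
            "total": result.summary.total,
        }
    if result.introns:
        lines = ["gene_id\tindex\tphase\ttype\tstart\tend"]
        for gene_id in sorted(result.introns):
            lines.extend(structure.introns_to_tsv(result.introns[gene_id]))
        (out / "introns.tsv").write_text("\n".join(lines) + "\n")
        report["intron_type_counts"] = {
            t: sum(
                1 for ii in result.introns.values() for i in ii if i.type == t
            )
            for t in ("R", "V", "other")
        }
    if result.duplication:
        report["duplication"] = {
            "clusters": result.duplication.clusters,
            "tandem_pairs": [dataclasses.asdict(p) for p in result.duplication.tandem_pairs],
            "segmental_pairs": [dataclasses.asdict(p) for p in result.duplication.segmental_pairs],
        }
    if result.tree_newick:
        (out / "family_tree.nwk").write_text(result.tree_newick + "\n")
    if result.element_hits:
        all_hits = [h for hits in result.element_hits.values() for h in hits]
        (out / "element_hits.tsv").write_text(promoters.hits_to_tsv(all_hits))
        report["n_element_hits"] = len(all_hits)
    if result.expression_call:
        report["expression"] = {
            "expressed": sorted(result.expression_call.expressed),
            "below_threshold": sorted(result.expression_call.below_threshold),
            "not_detected": sorted(result.expression_call.not_detected),
        }
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
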