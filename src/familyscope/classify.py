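"""Group/subgroup assignment, isoform collapsing and family summaries.

The classification rules mirror the standard WRKY scheme: two domains put a
protein in Group I; a single C2HC finger in Group III; a single C2H2 finger
with four residues between the cysteines in Group IIc.  A single C2H2 finger
with a longer spacer is compatible with IIa, IIb, IId and IIe alike — the
grammar cannot separate them, so the call falls to the nearest labeled
reference domain under the alignment p-distance (evidence is then
"grammar+phylogeny").  Proteins sharing a locus are isoforms collapsed to
one representative gene; identical proteins at different loci are flagged
redundant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from . import phylo
from .domains import WrkyDomain

GROUPS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III")

HARF_RE = re.compile(r"RTGHARFRR[AG]P")

_ISOFORM_RE = re.compile(r"^(?P<gene>.+)\.(?P<suffix>\d+)$")

#: Subgroups that share the single-domain C2H2 long-spacer signature.
AMBIGUOUS_SUBGROUPS = frozenset({"IIa", "IIb", "IId", "IIe"})


@dataclass
class FamilyRecord:
    protein_id: str
    gene_id: str
    sequence: str
    domains: list[WrkyDomain]
    group: str = "II-unresolved"
    evidence: str = "grammar"
    is_isoform_representative: bool = True
    n_isoforms: int = 1
    redundant_with: Optional[str] = None
    harf_present: bool = False


def gene_id_of(protein_id: str) -> str:
    """Locus id: the protein id with its trailing isoform suffix stripped."""
    m = _ISOFORM_RE.match(protein_id)
    return m.group("gene") if m else protein_id


def detect_harf(sequence: str) -> tuple[bool, Optional[int]]:
    """HARF motif RTGHARFRR(A/G)P, a Group IId hallmark."""
    m = HARF_RE.search(sequence)
    return (True, m.start()) if m else (False, None)


def assign_group(
    record: FamilyRecord,
    reference_set: Sequence[tuple[str, str, str]] = (),
) -> FamilyRecord:
    """Attach group label and evidence to a record with >=1 domain.

    ``reference_set`` holds (ref_id, group_label, domain_sequence) rows; only
    those labeled IIa/IIb/IId/IIe matter for the ambiguous C2H2 case.
    """
    if not record.domains:
        raise ValueError(f"{record.protein_id}: no domains, not a family member")
    group, evidence = _group_of(record, reference_set)
    record.group = group
    record.evidence = evidence
    record.harf_present = detect_harf(record.sequence)[0]
    return record


def _group_of(
    record: FamilyRecord, reference_set: Sequence[tuple[str, str, str]]
) -> tuple[str, str]:
    if len(record.domains) >= 2:
        return "I", "grammar"
    d = record.domains[0]
    zf = d.zinc_finger
    if zf is None:
        # Heptapeptide-only truncation: the grammar is silent; fall back to
        # the nearest reference over the full reference set when available.
        if reference_set:
            label, _ = phylo.nearest_reference(
                _domain_sequence(record, d), list(reference_set)
            )
            return label, "grammar+phylogeny"
        return "II-unresolved", "grammar"
    if zf.finger_class == "C2HC":
        return "III", "grammar"
    if zf.n1 == 4:
        return "IIc", "grammar"
    refs = [r for r in reference_set if r[1] in AMBIGUOUS_SUBGROUPS]
    if not refs:
        return "II-unresolved", "grammar"
    label, _ = phylo.nearest_reference(_domain_sequence(record, d), refs)
    return label, "grammar+phylogeny"


def _domain_sequence(record: FamilyRecord, d: WrkyDomain) -> str:
    return record.sequence[d.domain_start : d.domain_end + 1]


def collapse_isoforms(records: Sequence[FamilyRecord]) -> list[FamilyRecord]:
    """One representative per gene: the longest protein, ties to the lowest
    isoform suffix.  Identical sequences at different loci are kept but
    cross-flagged ``redundant_with``.  Conflicting isoform labels warn and
    the representative's label wins.
    """
    by_gene: dict[str, list[FamilyRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)

    out: list[FamilyRecord] = []
    for gene_id in sorted(by_gene):
        group = by_gene[gene_id]

        def sort_key(r: FamilyRecord):
            m = _ISOFORM_RE.match(r.protein_id)
            suffix = int(m.group("suffix")) if m else 0
            return (-len(r.sequence), suffix)

        rep = min(group, key=sort_key)
        labels = {r.group for r in group}
        if len(labels) > 1:
            import warnings

            warnings.warn(
                f"{gene_id}: isoforms disagree on group ({sorted(labels)}); "
                f"representative {rep.protein_id} wins",
                stacklevel=2,
            )
        rep = replace_fields(rep, is_isoform_representative=True, n_isoforms=len(group))
        out.append(rep)

    # Redundancy: identical sequences across distinct loci.
    by_seq: dict[str, list[int]] = {}
    for idx, rec in enumerate(out):
        by_seq.setdefault(rec.sequence, []).append(idx)
    for idxs in by_seq.values():
        if len(idxs) > 1:
            ids = [out[i].protein_id for i in idxs]
            for i in idxs:
                partner = next(p for p in ids if p != out[i].protein_id)
                out[i].redundant_with = partner
    return out


def replace_fields(rec: FamilyRecord, **kw) -> FamilyRecord:
    new = FamilyRecord(**{**rec.__dict__, **kw, "domains": rec.domains})
    return new


@dataclass(frozen=True)
class FamilySummary:
    counts: dict[str, int]
    percentages: dict[str, float]  # one decimal
    combined_IIa_IIb: int  # integer percent
    total: int


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize(counts_or_records) -> FamilySummary:
    """Per-group gene counts and percentage distribution.

    Accepts either grouped gene-level records or a mapping of group -> count.
    Percentages are 100*count/total rounded half-up to one decimal; the
    combined IIa+IIb share is rounded to the nearest integer percent.
    """
    if isinstance(counts_or_records, dict):
        counts = {g: int(counts_or_records.get(g, 0)) for g in GROUPS}
        extra = set(counts_or_records) - set(GROUPS)
        if extra:
            raise ValueError(f"unknown group labels: {sorted(extra)}")
    else:
        records = list(counts_or_records)
        if any(r.group not in GROUPS for r in records):
            bad = [r.protein_id for r in records if r.group not in GROUPS]
            raise ValueError(f"ungrouped records: {bad}")
        counts = {g: sum(1 for r in records if r.group == g) for g in GROUPS}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no grouped genes to summarize")
    percentages = {
        g: _round_half_up(100.0 * c / total, 1) for g, c in counts.items()
    }
    combined = int(
        _round_half_up(100.0 * (counts["IIa"] + counts["IIb"]) / total, 0)
    )
    return FamilySummary(counts, percentages, combined, total)


def records_to_tsv(records: Sequence[FamilyRecord]) -> str:
    """Table-1-style dump: one row per protein."""
    lines = [
        "protein_id\tgene_id\theptapeptides\tsignatures\tn_domains\tgroup"
        "\tevidence\tn_isoforms\tredundant_with\tharf"
    ]
    for r in records:
        heptas = "/".join(
            d.heptapeptide.variant if d.heptapeptide else "-" for d in r.domains
        )
        sigs = "/".join(d.signature or "-" for d in r.domains)
        lines.append(
            f"{r.protein_id}\t{r.gene_id}\t{heptas}\t{sigs}\t{len(r.domains)}"
            f"\t{r.group}\t{r.evidence}\t{r.n_isoforms}"
            f"\t{r.redundant_with or '-'}\t{int(r.harf_present)}"
        )
    return "\n".join(lines) + "\n"
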