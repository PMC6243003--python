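"""Default synthetic study design.

``default_spec`` lays out a 200-gene WRKY complement (every group and
subgroup, the observed heptapeptide and zinc-finger signature variants,
truncated domains, isoforms, both strands) plus 100 non-WRKY decoys over
eight chromosomes and one scaffold.  Regular genes sit 210 kb apart —
farther than the 200 kb cluster window — so the only clusters, tandem pairs
and segmental duplicates are the declared islands:

* chr1: tandem pair 30 kb apart, zero spacer genes.
* chr2: tandem pair 80 kb apart with three decoy spacer genes.
* chr3: a three-gene cluster chained at 180 kb gaps (no tandem pair).
* chr5: a 120 kb pair — a cluster but beyond the tandem window.
* scaffold_1: tandem pair 20 kb apart with one spacer gene.
* two genes on chr1 duplicated as an identical block on chr4 (segmental).
"""

from __future__ import annotations

from .synth import DecoyGene, DomainPlan, IntronPlan, PlantedGene, SyntheticSpec

GROUP_PATTERN = (
    "I", "IIc", "IIb", "III", "IIe", "IIc", "IId",
    "I", "IIc", "IIa", "IIb", "IIc", "IIe", "III",
)

_FPKM_CYCLE = (
    [12.5, 0.0, 3.2, 56.7],
    [0.85, 0.1, 0.0, 7.4],
    [0.5, 0.0, 0.0, 0.2],
    [22.1, 14.3, 0.9, 2.2],
    [0.4, 0.49, 0.0, 0.1],
    [0.0, 0.0, 0.0, 0.0],
    [5.6, 0.0, 0.0, 1.1],
    [0.0, 0.0, 0.0, 0.0],
)

_ELEMENT_CYCLE = (
    [("ABRELATERD1", -1200, "+")],
    [("DPBFCOREDCDC3", -800, "+"), ("WBOXATNPR1", -300, "-")],
    [("ERELEE4", -1400, "+"), ("PREATPRODH", -650, "+")],
    [("DRECRTCOREAT", -500, "+")],
    [("MYBCORE", -1000, "-"), ("GT1CONSENSUS", -200, "+")],
    [("WBOXNTERF3", -350, "+")],
)

#: Variant heptapeptides are a IIc specialty in both Vigna families.
_IIC_VARIANTS = ("WRKYGKK", "WRKYGEK", "SRKYGQK", "WKKYGQK")

SPACING = 210_000  # regular start-to-start gap, beyond the cluster window
FIRST_START = 20_000
CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 9)) + ("scaffold_1",)


def _gene(gene_id: str, group: str, index: int, k: int) -> PlantedGene:
    """Template gene for a group.

    ``index`` is the global gene index (drives strand, promoter elements,
    expression and isoform variation); ``k`` is the occurrence number within
    the group (drives group-specific features such as variant signatures).
    """
    if group == "I":
        domains = [
            DomainPlan("I-NTWD", "WRKYGQK", 4, 22, "H"),
            DomainPlan("I-CTWD", "WRKYGQK", 4, 23, "H"),
        ]
        introns = [IntronPlan("R", domain_index=1),
                   IntronPlan("other", phase=1, tail_residue=8)]
    elif group == "IIa":
        domains = [DomainPlan("IIa", "WRKYGQK", 5, 23, "H")]
        introns = [IntronPlan("V"), IntronPlan("other", phase=1, tail_residue=8)]
    elif group == "IIb":
        n2 = 30 if k % 25 == 2 else 23  # the CX5CX30HXH outlier
        domains = [DomainPlan("IIb", "WRKYGQK", 5, n2, "H")]
        introns = [IntronPlan("V"), IntronPlan("other", phase=0, tail_residue=12)]
    elif group == "IIc":
        hepta = "WRKYGQK"
        if k % 5 == 3:
            hepta = _IIC_VARIANTS[(k // 5) % len(_IIC_VARIANTS)]
        n2 = 22 if k % 50 == 1 else 23  # rare CX4CX22HXH variant
        domains = [DomainPlan("IIc", hepta, 4, n2, "H")]
        introns = [] if k % 50 == 7 else [IntronPlan("R")]  # one intronless
        if k % 50 == 9:  # finger-only truncation
            domains = [DomainPlan("IIc", None, 4, 23, "H")]
            introns = []
    elif group == "IId":
        domains = [DomainPlan("IId", "WRKYGQK", 5, 23, "H")]
        introns = [IntronPlan("R"), IntronPlan("other", phase=2, tail_residue=10)]
    elif group == "IIe":
        domains = [DomainPlan("IIe", "WRKYGQK", 5, 23, "H")]
        introns = [IntronPlan("R")]
    elif group == "III":
        n1 = 6 if k % 25 == 2 else 7  # the CX6CX23HXC variant
        domains = [DomainPlan("III", "WRKYGQK", n1, 23, "C")]
        introns = [IntronPlan("R"), IntronPlan("other", phase=0, tail_residue=10)]
        if k % 50 == 4:  # finger-only truncation
            domains = [DomainPlan("III", None, 7, 23, "C")]
            introns = []
    else:
        raise ValueError(group)
    return PlantedGene(
        gene_id,
        group,
        domains,
        introns=introns,
        strand="-" if index % 3 == 2 else "+",
        promoter_elements=[
            tuple(e) for e in _ELEMENT_CYCLE[(index // 2) % len(_ELEMENT_CYCLE)]
        ]
        if index % 2 == 0
        else [],
        fpkm=list(_FPKM_CYCLE[index % len(_FPKM_CYCLE)]),
        harf=(group == "IId" and k % 7 != 0),
        n_isoforms=4 if index % 97 == 13 else (2 if index % 97 == 27 else 1),
    )


def default_spec(seed: int, n_wrky: int = 200, n_decoys: int = 100) -> SyntheticSpec:
    """The standard synthetic study: declared islands plus regular genes."""
    if n_wrky < 15:
        raise ValueError("the default design needs at least 15 planted genes")
    genes: list[PlantedGene] = []
    decoys: list[DecoyGene] = []
    clusters: list[list[str]] = []
    tandem_pairs: list[tuple[str, str, int, int]] = []
    segmental_pairs: list[tuple[str, str]] = []

    cursors = {c: FIRST_START for c in CHROMOSOMES}
    group_counts: dict[str, int] = {}
    idx = 0

    def next_gene(seq_id: str, start: int, group_override: str | None = None) -> PlantedGene:
        nonlocal idx
        group = group_override or GROUP_PATTERN[idx % len(GROUP_PATTERN)]
        k = group_counts.get(group, 0)
        group_counts[group] = k + 1
        g = _gene(f"W{idx + 1:03d}", group, idx, k)
        g.seq_id = seq_id
        g.start = start
        cursors[seq_id] = max(cursors[seq_id], start) + SPACING
        genes.append(g)
        idx += 1
        return g

    # --- islands ----------------------------------------------------------
    a = next_gene("chr1", 100_000, "IIc")
    b = next_gene("chr1", 130_000, "IIc")
    tandem_pairs.append((a.gene_id, b.gene_id, 30_000, 0))
    clusters.append([a.gene_id, b.gene_id])

    a = next_gene("chr2", 100_000, "IIe")
    b = next_gene("chr2", 180_000, "IIe")
    tandem_pairs.append((a.gene_id, b.gene_id, 80_000, 3))
    clusters.append([a.gene_id, b.gene_id])
    for pos in (110_000, 130_000, 150_000):
        decoys.append(DecoyGene(f"D{len(decoys) + 1:03d}", "chr2", pos))

    trio = [
        next_gene("chr3", 100_000, "III"),
        next_gene("chr3", 280_000, "III"),
        next_gene("chr3", 460_000, "III"),
    ]
    clusters.append([g.gene_id for g in trio])

    a = next_gene("chr5", 100_000, "IId")
    b = next_gene("chr5", 220_000, "IId")
    clusters.append([a.gene_id, b.gene_id])

    a = next_gene("scaffold_1", 50_000, "IIb")
    b = next_gene("scaffold_1", 70_000, "IIb")
    tandem_pairs.append((a.gene_id, b.gene_id, 20_000, 1))
    clusters.append([a.gene_id, b.gene_id])
    decoys.append(DecoyGene(f"D{len(decoys) + 1:03d}", "scaffold_1", 58_000))

    # Segmental block: two genes on chr1 copied to chr4 as identical proteins.
    src1 = next_gene("chr1", cursors["chr1"], "IIc")
    src2 = next_gene("chr1", cursors["chr1"], "IIe")
    cp1 = next_gene("chr4", cursors["chr4"], "IIc")
    cp2 = next_gene("chr4", cursors["chr4"], "IIe")
    for src, cp in ((src1, cp1), (src2, cp2)):
        cp.copy_of = src.gene_id
        cp.domains, cp.introns = src.domains, src.introns
        cp.strand = src.strand
        cp.n_isoforms = 1
        segmental_pairs.append((src.gene_id, cp.gene_id))

    # --- regular genes ----------------------------------------------------
    while idx < n_wrky:
        seq_id = CHROMOSOMES[idx % len(CHROMOSOMES)]
        next_gene(seq_id, cursors[seq_id])

    # Remaining decoys, placed beyond the gene slots.
    di = len(decoys)
    k = 0
    while di < n_decoys:
        seq_id = CHROMOSOMES[k % len(CHROMOSOMES)]
        pos = cursors[seq_id] + 40_000
        decoys.append(
            DecoyGene(f"D{di + 1:03d}", seq_id, pos, strand="-" if di % 4 == 1 else "+")
        )
        cursors[seq_id] = pos + 60_000
        di += 1
        k += 1

    chromosomes = {c: cursors[c] + SPACING for c in CHROMOSOMES}
    return SyntheticSpec(
        seed=seed,
        chromosomes=chromosomes,
        genes=genes,
        decoys=decoys,
        clusters=clusters,
        tandem_pairs=tandem_pairs,
        segmental_pairs=segmental_pairs,
    )
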