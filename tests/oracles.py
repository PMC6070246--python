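"""Brute-force reference implementations used only as test oracles.

Everything here trades efficiency for obviousness: linear scans over all
genes, explicit per-base membership sets, and full membership enumeration.
The production code must agree with these on every input.
"""

from __future__ import annotations

from itertools import combinations

from lncpair.gene_models import GeneModel, GenomicInterval, LncRNALocus


def brute_overlap(genes: dict[str, GeneModel], chrom: str,
                  start: int, end: int) -> set[str]:
    return {
        g.gene_id for g in genes.values()
        if g.chrom == chrom and g.span.start < end and start < g.span.end
    }


def brute_unsigned_distance(gene: GeneModel, pos: int) -> int:
    if gene.span.start <= pos < gene.span.end:
        return 0
    if pos < gene.span.start:
        return gene.span.start - pos
    return pos - gene.span.end + 1


def brute_nearest(genes: dict[str, GeneModel], chrom: str,
                  pos: int) -> tuple[str, int] | None:
    candidates = [
        (brute_unsigned_distance(g, pos), g.gene_id)
        for g in genes.values() if g.chrom == chrom
    ]
    if not candidates:
        return None
    dist, gid = min(candidates)
    return gid, dist


def brute_category(lnc: LncRNALocus, genes: dict[str, GeneModel],
                   upstream: int = 5000, downstream: int = 1000,
                   ) -> tuple[str | None, str]:
    """Per-base classification of a lncRNA anchor against the closest gene."""
    hit = brute_nearest(genes, lnc.chrom, lnc.anchor)
    if hit is None:
        return None, "intergenic"
    gid, dist = hit
    gene = genes[gid]
    anchor = lnc.anchor
    if dist == 0:
        exon_bases: set[int] = set()
        for exon in gene.exons:
            exon_bases.update(range(exon.start, exon.end))
        if anchor not in exon_bases:
            return gid, "intron"
        if gene.cds_start is None:
            return gid, "exon"
        cds_bases = set(range(gene.cds_start, gene.cds_end))
        if anchor in cds_bases:
            return gid, "exon"
        # exonic but outside the CDS: which UTR, in the gene's reading direction
        before_cds = anchor < gene.cds_start
        if gene.strand == "+":
            return gid, "utr5" if before_cds else "utr3"
        return gid, "utr3" if before_cds else "utr5"
    # outside the span: upstream side is the TSS side of the gene
    on_low_side = anchor < gene.span.start
    upstream_side = on_low_side if gene.strand == "+" else not on_low_side
    if upstream_side and dist <= upstream:
        return gid, "upstream"
    if not upstream_side and dist <= downstream:
        return gid, "downstream"
    return gid, "intergenic"


def brute_venn(sets: dict[str, set]) -> dict[frozenset, set]:
    names = sorted(sets)
    regions: dict[frozenset, set] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            combo_set = frozenset(combo)
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names
                                         if n not in combo_set))
            regions[combo_set] = inside - outside
    return regions


def mirror_interval(iv: GenomicInterval, length: int) -> GenomicInterval:
    strand = {"+": "-", "-": "+"}.get(iv.strand, iv.strand)
    return GenomicInterval(iv.chrom, length - iv.end, length - iv.start, strand)


def mirror_gene(gene: GeneModel, length: int) -> GeneModel:
    exons = tuple(sorted(
        (mirror_interval(e, length) for e in gene.exons),
        key=lambda iv: iv.start,
    ))
    cds_start = cds_end = None
    if gene.cds_start is not None:
        cds_start, cds_end = length - gene.cds_end, length - gene.cds_start
    return GeneModel(
        gene_id=gene.gene_id,
        span=mirror_interval(gene.span, length),
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )


def mirror_lnc(lnc: LncRNALocus, length: int) -> LncRNALocus:
    return LncRNALocus(lnc.lnc_id, mirror_interval(lnc.span, length))
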