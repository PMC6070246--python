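import numpy as np
import pytest

from lncpair.gene_models import GeneModel, GenomicInterval, LncRNALocus, build_index
from lncpair.genomic_annotation import (
    Category,
    annotate_all,
    categorize,
    category_distribution,
    closest_pcg,
    signed_distance,
)
from lncpair.simulate import SimulationConfig, generate_genome
from oracles import brute_category, brute_nearest, mirror_gene, mirror_lnc


def shift_gene(gene, offset):
    span = GenomicInterval(gene.chrom, gene.span.start + offset,
                           gene.span.end + offset, gene.strand)
    exons = tuple(
        GenomicInterval(e.chrom, e.start + offset, e.end + offset, gene.strand)
        for e in gene.exons
    )
    cds_start = None if gene.cds_start is None else gene.cds_start + offset
    cds_end = None if gene.cds_end is None else gene.cds_end + offset
    return GeneModel(gene.gene_id, span, exons, cds_start, cds_end)


def lnc_at(anchor, chrom="chr1", strand="+", length=100):
    if strand == "+":
        span = GenomicInterval(chrom, anchor, anchor + length, "+")
    else:
        span = GenomicInterval(chrom, anchor - length + 1, anchor + 1, "-")
    return LncRNALocus("L", span)


class TestCategorize:
    """Worked example: + strand gene, exons [100,200)+[400,500), CDS [150,450)."""

    def test_intron_anchor(self, worked_gene):
        assert categorize(lnc_at(300), worked_gene) is Category.INTRON

    def test_exonic_five_prime_of_cds_is_utr5(self, worked_gene):
        assert categorize(lnc_at(120), worked_gene) is Category.UTR5

    def test_exonic_three_prime_of_cds_is_utr3(self, worked_gene):
        assert categorize(lnc_at(470), worked_gene) is Category.UTR3

    def test_exonic_inside_cds_is_exon(self, worked_gene):
        assert categorize(lnc_at(160), worked_gene) is Category.EXON

    def test_no_cds_exonic_anchor_is_exon(self, worked_gene):
        no_cds = GeneModel("G1", worked_gene.span, worked_gene.exons)
        assert categorize(lnc_at(120), no_cds) is Category.EXON

    @pytest.mark.parametrize(
        "offset,expected",
        [(5000, Category.UPSTREAM), (5001, Category.INTERGENIC)],
    )
    def test_upstream_window_boundary_inclusive(self, worked_gene, offset, expected):
        gene = shift_gene(worked_gene, 20_000)
        lnc = lnc_at(gene.span.start - offset)
        assert categorize(lnc, gene) is expected

    @pytest.mark.parametrize(
        "offset,expected",
        [(1000, Category.DOWNSTREAM), (1001, Category.INTERGENIC)],
    )
    def test_downstream_window_boundary_inclusive(self, worked_gene, offset, expected):
        lnc = lnc_at(worked_gene.span.end - 1 + offset)
        assert categorize(lnc, worked_gene) is expected

    def test_lncrna_own_strand_does_not_change_category(self, worked_gene):
        for strand in ("+", "-"):
            assert categorize(lnc_at(300, strand=strand), worked_gene) is Category.INTRON

    def test_no_gene_on_chromosome_is_intergenic(self):
        assert categorize(lnc_at(10), None) is Category.INTERGENIC

    def test_nonpositive_window_rejected(self, worked_gene):
        with pytest.raises(ValueError):
            categorize(lnc_at(300), worked_gene, upstream_window=0)

    def test_minus_strand_gene_mirror_of_plus(self, worked_gene):
        """Reflecting the whole configuration must preserve every category."""
        gene = shift_gene(worked_gene, 20_000)
        L = 60_000
        mirrored_gene = mirror_gene(gene, L)
        for anchor in [20_300, 20_120, 20_470, 20_160,
                       gene.span.start - 5000,
                       gene.span.start - 5001,
                       gene.span.end - 1 + 1000,
                       gene.span.end - 1 + 1001]:
            forward = categorize(lnc_at(anchor), gene)
            mirrored = categorize(
                mirror_lnc(lnc_at(anchor), L), mirrored_gene
            )
            assert mirrored is forward, f"anchor {anchor}"


class TestSignedDistance:
    def make_gene(self, strand):
        span = GenomicInterval("chr1", 1000, 2000, strand)
        return GeneModel("G", span, (GenomicInterval("chr1", 1000, 2000, strand),))

    def test_inside_span_is_zero(self):
        assert signed_distance(1500, self.make_gene("+")) == 0

    @pytest.mark.parametrize("strand,pos,expected", [
        ("+", 999, -1), ("+", 2000, 1),   # upstream negative, downstream positive
        ("-", 999, 1), ("-", 2000, -1),   # strand frame flips the sides
    ])
    def test_sign_follows_gene_strand_frame(self, strand, pos, expected):
        assert signed_distance(pos, self.make_gene(strand)) == expected


class TestClosestPCG:
    def test_prefers_nearer_gene(self):
        a = GeneModel("A", GenomicInterval("chr1", 1000, 2000, "+"),
                      (GenomicInterval("chr1", 1000, 2000, "+"),))
        b = GeneModel("B", GenomicInterval("chr1", 3000, 4000, "+"),
                      (GenomicInterval("chr1", 3000, 4000, "+"),))
        index = build_index([a, b])
        gene_id, dist = closest_pcg(lnc_at(2300), index)
        assert gene_id == "A"
        assert dist == 301  # 301 bp past the downstream edge of A

    def test_tie_breaks_to_lexicographically_smaller_id(self):
        a = GeneModel("B", GenomicInterval("chr1", 0, 100, "+"),
                      (GenomicInterval("chr1", 0, 100, "+"),))
        b = GeneModel("A", GenomicInterval("chr1", 200, 300, "+"),
                      (GenomicInterval("chr1", 200, 300, "+"),))
        # anchor 149: 50 bp from A's start (200-149-... ) vs 50 from B's end
        index = build_index([a, b])
        gene_id, _ = closest_pcg(lnc_at(149), index)
        # distances: to B (span 0-100): 149-100+1 = 50; to A (span 200-300): 51
        assert gene_id == "B"
        gene_id2, _ = closest_pcg(lnc_at(150), index)
        # both 50/51 flip: to B 51, to A 50
        assert gene_id2 == "A"

    def test_matches_linear_scan_on_random_instances(self):
        rng = np.random.default_rng(21)
        genes = {}
        for i in range(40):
            gid = f"G{i:02d}"
            chrom = f"chr{1 + i % 2}"
            start = int(rng.integers(0, 80_000))
            end = start + int(rng.integers(300, 4000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes[gid] = GeneModel(
                gid, GenomicInterval(chrom, start, end, strand),
                (GenomicInterval(chrom, start, end, strand),))
        index = build_index(genes)
        for j in range(100):
            chrom = f"chr{1 + j % 2}"
            anchor = int(rng.integers(0, 90_000))
            lnc = lnc_at(anchor, chrom=chrom)
            gene_id, signed = closest_pcg(lnc, index)
            expected_id, expected_dist = brute_nearest(genes, chrom, anchor)
            assert gene_id == expected_id
            assert abs(signed) == expected_dist


class TestAnnotateAll:
    def test_recovers_planted_categories_exactly(self, bundle):
        records = annotate_all(bundle.lncs.values(), bundle.genes)
        for record in records:
            assert record.category is bundle.truth.lnc_category[record.lnc_id]

    def test_empty_lncrna_set(self, bundle):
        assert annotate_all([], bundle.genes) == []

    def test_agreement_with_per_base_brute_force(self, bundle):
        records = annotate_all(bundle.lncs.values(), bundle.genes)
        for record in records:
            lnc = bundle.lncs[record.lnc_id]
            gid, cat = brute_category(lnc, bundle.genes)
            assert record.category.value == cat
            if cat != "intergenic":
                assert record.closest_gene_id == gid

    def test_strand_mirror_invariance(self):
        config = SimulationConfig(n_genes=40, n_lncrnas=200, seed=8)
        genes, lncs, truth = generate_genome(config)
        L = max(g.span.end for g in genes.values()) + 10_000
        forward = {r.lnc_id: r.category
                   for r in annotate_all(lncs.values(), genes)}
        mirrored_genes = [mirror_gene(g, L) for g in genes.values()]
        mirrored_lncs = [mirror_lnc(l, L) for l in lncs.values()]
        mirrored = {r.lnc_id: r.category
                    for r in annotate_all(mirrored_lncs, mirrored_genes)}
        assert mirrored == forward


class TestCategoryDistribution:
    def make_records(self):
        from lncpair.genomic_annotation import AnnotationRecord
        cats = [Category.INTRON, Category.INTRON, Category.UTR3, Category.INTERGENIC]
        return [
            AnnotationRecord(f"L{i}", None if c is Category.INTERGENIC else "G",
                             0 if c is not Category.INTERGENIC else None, c)
            for i, c in enumerate(cats)
        ]

    def test_counts_and_percentages(self):
        dist = category_distribution(self.make_records())
        assert dist.counts["intron"] == 2
        assert dist.percentages["intron"] == 50
        assert dist.percentages["utr3"] == 25
        assert dist.percentages["intergenic"] == 25
        assert sum(dist.counts.values()) == 4

    def test_empty_subset_all_zero(self):
        dist = category_distribution(self.make_records(), subset=[])
        assert all(v == 0 for v in dist.counts.values())
        assert dist.total == 0

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            category_distribution(self.make_records(), subset=["ghost"])
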