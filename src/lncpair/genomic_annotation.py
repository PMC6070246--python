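"""Strand-aware categorization of lncRNAs relative to their closest coding gene.

Each lncRNA is filed into exactly one of seven categories by the position of
its 5' anchor relative to the closest protein-coding gene: within 5 kb
upstream of the TSS, 5'-UTR, exonic, intronic, 3'-UTR, within 1 kb
downstream of the TTS, or intergenic.  Upstream/downstream are measured in
the *gene's* strand frame; the lncRNA's own strand never changes the
category (an antisense overlap classifies by position).  Windows are
inclusive at exactly 5000 / 1000 bp.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .gene_models import FeatureIndex, GeneModel, LncRNALocus, build_index

__all__ = [
    "Category",
    "AnnotationRecord",
    "CategoryDistribution",
    "UPSTREAM_WINDOW",
    "DOWNSTREAM_WINDOW",
    "signed_distance",
    "closest_pcg",
    "categorize",
    "annotate_all",
    "annotation_frame",
    "category_distribution",
]

UPSTREAM_WINDOW = 5000
DOWNSTREAM_WINDOW = 1000


class Category(str, enum.Enum):
    UPSTREAM = "upstream"
    UTR5 = "utr5"
    EXON = "exon"
    INTRON = "intron"
    UTR3 = "utr3"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AnnotationRecord:
    """One lncRNA's closest coding gene, signed distance, and category.

    ``distance`` is 0 when the anchor lies inside the gene span, negative by
    d bp when the anchor sits d bp upstream of the TSS (gene strand frame),
    and positive downstream of the TTS.  ``body_overlaps_gene`` records
    whether the lncRNA span overlaps the closest gene's span at all — used
    by pair identification, not by the category.
    """

    lnc_id: str
    closest_gene_id: Optional[str]
    distance: Optional[int]
    category: Category
    body_overlaps_gene: bool = False

    def __post_init__(self) -> None:
        if self.category is not Category.INTERGENIC and self.closest_gene_id is None:
            raise ValueError(
                f"{self.lnc_id}: non-intergenic record requires a closest gene"
            )


def signed_distance(anchor: int, gene: GeneModel) -> int:
    """Signed bp offset from an anchor position to a gene span, strand-aware.

    0 inside the span; -d when d bp off the TSS side; +d when d bp off the
    TTS side (d = 1 for the first base outside the span).
    """
    s, e = gene.span.start, gene.span.end
    if s <= anchor < e:
        return 0
    if anchor < s:
        d = s - anchor
        return -d if gene.strand == "+" else d
    d = anchor - e + 1
    return d if gene.strand == "+" else -d


def closest_pcg(lnc: LncRNALocus,
                index: FeatureIndex) -> tuple[Optional[str], Optional[int]]:
    """Closest gene to the lncRNA anchor and the signed distance to it.

    The closest gene minimizes the unsigned anchor-to-span distance; ties go
    to the lexicographically smallest gene id.  On a chromosome without
    genes both return values are None.
    """
    hit = index.nearest(lnc.chrom, lnc.anchor)
    if hit is None:
        return None, None
    gene, _ = hit
    return gene.gene_id, signed_distance(lnc.anchor, gene)


def categorize(lnc: LncRNALocus, gene: Optional[GeneModel],
               distance: Optional[int] = None,
               upstream_window: int = UPSTREAM_WINDOW,
               downstream_window: int = DOWNSTREAM_WINDOW) -> Category:
    """Category of a lncRNA relative to its closest gene, by its 5' anchor.

    Inside the span: intron when the anchor falls between exons; in an exon
    the CDS splits the call into utr5 / exon / utr3 on the gene's strand
    (exon when the gene has no CDS).  Outside: upstream/downstream when the
    anchor is within the inclusive windows off the TSS/TTS; else intergenic.
    """
    if upstream_window <= 0 or downstream_window <= 0:
        raise ValueError("annotation windows must be positive")
    if gene is None:
        return Category.INTERGENIC
    anchor = lnc.anchor
    if distance is None:
        distance = signed_distance(anchor, gene)

    if distance == 0:
        if not gene.exonic_at(anchor):
            return Category.INTRON
        if not gene.has_cds:
            return Category.EXON
        if gene.strand == "+":
            if anchor < gene.cds_start:
                return Category.UTR5
            if anchor >= gene.cds_end:
                return Category.UTR3
        else:
            if anchor >= gene.cds_end:
                return Category.UTR5
            if anchor < gene.cds_start:
                return Category.UTR3
        return Category.EXON
    if distance < 0 and -distance <= upstream_window:
        return Category.UPSTREAM
    if distance > 0 and distance <= downstream_window:
        return Category.DOWNSTREAM
    return Category.INTERGENIC


def annotate_all(lncs: Iterable[LncRNALocus],
                 genes: Iterable[GeneModel] | Mapping[str, GeneModel] | FeatureIndex,
                 upstream_window: int = UPSTREAM_WINDOW,
                 downstream_window: int = DOWNSTREAM_WINDOW) -> list[AnnotationRecord]:
    """Annotate every lncRNA against its closest coding gene.

    The "annotated" subset downstream is the records whose category is not
    intergenic.
    """
    index = genes if isinstance(genes, FeatureIndex) else build_index(genes)
    records = []
    for lnc in sorted(lncs, key=lambda l: l.lnc_id):
        gene_id, distance = closest_pcg(lnc, index)
        gene = index.get(gene_id) if gene_id is not None else None
        category = categorize(lnc, gene, distance,
                              upstream_window, downstream_window)
        overlaps = bool(gene is not None and lnc.span.overlaps(gene.span))
        records.append(AnnotationRecord(
            lnc_id=lnc.lnc_id,
            closest_gene_id=gene_id,
            distance=distance,
            category=category,
            body_overlaps_gene=overlaps,
        ))
    return records


def annotation_frame(records: Iterable[AnnotationRecord]) -> pd.DataFrame:
    rows = [
        (r.lnc_id, r.closest_gene_id, r.distance, r.category.value,
         r.body_overlaps_gene)
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["lnc_id", "closest_gene", "distance", "category",
                 "body_overlaps_gene"],
    )


@dataclass(frozen=True)
class CategoryDistribution:
    """Counts and integer-rounded percentages per category over a record set."""

    counts: dict[str, int]
    percentages: dict[str, int]
    total: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "category": [c.value for c in Category],
            "count": [self.counts[c.value] for c in Category],
            "percent": [self.percentages[c.value] for c in Category],
        })


def category_distribution(records: Sequence[AnnotationRecord],
                          subset: Optional[Iterable[str]] = None) -> CategoryDistribution:
    """Category counts/percentages over the records, optionally restricted to
    a subset of lncRNA ids (e.g. the DE set of one comparison)."""
    by_id = {r.lnc_id: r for r in records}
    if subset is None:
        chosen = list(by_id)
    else:
        chosen = list(subset)
        unknown = [i for i in chosen if i not in by_id]
        if unknown:
            raise ValueError(f"ids not present in annotation records: {unknown[:5]}")
    counts = {c.value: 0 for c in Category}
    for lnc_id in chosen:
        counts[by_id[lnc_id].category.value] += 1
    total = len(chosen)
    percentages = {
        c: (round(100.0 * n / total) if total else 0) for c, n in counts.items()
    }
    return CategoryDistribution(counts=counts, percentages=percentages, total=total)
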