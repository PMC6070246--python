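"""lncRNA / coding-gene pair identification and the per-comparison counting chain.

A pair (L, G) is emitted for a comparison when:

1. G is L's closest coding gene and L either overlaps G's span or has its
   5' anchor within 5 kb upstream of the TSS / 1 kb downstream of the TTS
   (i.e. L's category is non-intergenic, or L's body overlaps G); and
2. both L and G are significantly differentially expressed in that
   comparison.

Direction concordance (same / opposite) is reported but is not a pairing
criterion.  Pairing is restricted to the closest gene, so each lncRNA
yields at most one pair per comparison; one gene may appear in several
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression import DEResult
from .genomic_annotation import AnnotationRecord, Category

__all__ = [
    "PairRecord",
    "identify_pairs",
    "pairs_frame",
    "pair_counting_chain",
]


@dataclass(frozen=True)
class PairRecord:
    """One (lncRNA, gene, comparison) pair passing both pairing criteria."""

    lnc_id: str
    gene_id: str
    comparison: str
    lnc_direction: str  # "up" or "down"
    gene_direction: str  # "up" or "down"
    category: Category
    distance: int

    def __post_init__(self) -> None:
        for d in (self.lnc_direction, self.gene_direction):
            if d not in ("up", "down"):
                raise ValueError(f"pair member direction must be up/down, got {d!r}")

    @property
    def concordance(self) -> str:
        return "same" if self.lnc_direction == self.gene_direction else "opposite"


def _significant_by_feature(results: Iterable[DEResult],
                            comparison: str) -> dict[str, DEResult]:
    found_comparison = False
    sig: dict[str, DEResult] = {}
    for r in results:
        if r.comparison != comparison:
            continue
        found_comparison = True
        if r.significant:
            sig[r.feature_id] = r
    if not found_comparison:
        raise ValueError(f"no DE results for comparison {comparison!r}")
    return sig


def identify_pairs(annotations: Sequence[AnnotationRecord],
                   lnc_de: Iterable[DEResult],
                   gene_de: Iterable[DEResult],
                   comparison: str) -> list[PairRecord]:
    """All lncRNA-gene pairs for one comparison, sorted by lncRNA id."""
    lnc_sig = _significant_by_feature(lnc_de, comparison)
    gene_sig = _significant_by_feature(gene_de, comparison)
    annotation_by_id = {a.lnc_id: a for a in annotations}

    pairs: list[PairRecord] = []
    for lnc_id in sorted(lnc_sig):
        record = annotation_by_id.get(lnc_id)
        if record is None or record.closest_gene_id is None:
            continue
        criterion1 = (record.category is not Category.INTERGENIC
                      or record.body_overlaps_gene)
        if not criterion1:
            continue
        gene_result = gene_sig.get(record.closest_gene_id)
        if gene_result is None:
            continue
        pairs.append(PairRecord(
            lnc_id=lnc_id,
            gene_id=record.closest_gene_id,
            comparison=comparison,
            lnc_direction=lnc_sig[lnc_id].direction,
            gene_direction=gene_result.direction,
            category=record.category,
            distance=record.distance,
        ))
    return pairs


def pairs_frame(pairs: Iterable[PairRecord]) -> pd.DataFrame:
    rows = [
        (p.lnc_id, p.gene_id, p.comparison, p.lnc_direction, p.gene_direction,
         p.concordance, p.category.value, p.distance)
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=[
        "lnc_id", "gene_id", "comparison", "lnc_direction", "gene_direction",
        "concordance", "category", "distance",
    ])


def pair_counting_chain(lnc_de_by_comparison: Mapping[str, Iterable[DEResult]],
                        annotations: Sequence[AnnotationRecord],
                        pairs_by_comparison: Mapping[str, Sequence[PairRecord]],
                        ) -> pd.DataFrame:
    """Per-comparison funnel: DE lncRNAs -> non-intergenic subset -> paired.

    Each stage is a subset of the previous one, so every column is monotone
    non-increasing down the chain.
    """
    annotation_by_id = {a.lnc_id: a for a in annotations}
    rows = {}
    for comparison, results in lnc_de_by_comparison.items():
        de_ids = {r.feature_id for r in results
                  if r.comparison == comparison and r.significant}
        annotated_ids = {
            i for i in de_ids
            if i in annotation_by_id
            and annotation_by_id[i].category is not Category.INTERGENIC
        }
        paired_lncs = {p.lnc_id for p in pairs_by_comparison.get(comparison, ())}
        n_pairs = len(annotated_ids & paired_lncs)
        rows[comparison] = (len(de_ids), len(annotated_ids), n_pairs)
    frame = pd.DataFrame(
        rows, index=["lncRNAs_differentially_regulated", "annotated_lncRNAs",
                     "lncRNA_PCG_pairs"],
    )
    return frame
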